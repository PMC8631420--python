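"""Loaders for the packaged reference frequency tables.

Small published summary tables ship with the package as CSV fixtures:
the over-60 trial-vs-self-report comparison, the Argentinian passive
registry comparison and its overall severity totals, the trial's
source-vocabulary table (a synthetic split consistent with the published
aggregates), and the eight-vaccine six-symptom profile table.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import VaccineProfile, load_profiles
from .stats import FrequencyTable

#: Over-60 sample sizes of the two compared cohorts.
TRIAL_OVER60_N = 1029
TELEGRAM_OVER60_N = 690

#: Self-report posts with at least one AE (registry-comparison base).
TELEGRAM_ANY_AE_N = 7797


def _path(name: str) -> Path:
    return Path(str(files("vigitext.data") / name))


def load_trial_comparison() -> pd.DataFrame:
    """Published over-60 comparison: trial vs self-report counts/percents."""
    return pd.read_csv(_path("table4_comparison.csv"), comment="#")


def trial_comparison_tables() -> tuple[FrequencyTable, FrequencyTable, pd.DataFrame]:
    """(telegram_over60, trial) frequency tables plus the raw frame."""
    df = load_trial_comparison()
    cats = tuple(df["category"])
    telegram = FrequencyTable(
        cats, df["telegram_count"].to_numpy(int), TELEGRAM_OVER60_N
    )
    trial = FrequencyTable(cats, df["trial_count"].to_numpy(int), TRIAL_OVER60_N)
    return telegram, trial, df


def load_registry_comparison() -> pd.DataFrame:
    """Published registry-vs-self-report comparison (printed values).

    The printed counts and percentages of this table are not mutually
    consistent; the percentage columns are taken at face value for
    correlation work and the count columns are carried verbatim.
    """
    return pd.read_csv(_path("table5_comparison.csv"), comment="#")


def load_registry_totals() -> FrequencyTable:
    """Overall registry totals: mild events out of all reported events."""
    return FrequencyTable.from_csv(_path("argentinian_registry_totals.csv"))


def load_trial_source_table() -> FrequencyTable:
    """Trial source-vocabulary table (synthetic split, published sums)."""
    return FrequencyTable.from_csv(_path("moscow_trial_over60_synthetic.csv"))


def load_vaccine_profiles() -> list[VaccineProfile]:
    """Eight-vaccine six-symptom percentage profiles."""
    return load_profiles(_path("vaccine_profiles.csv"))


def sputnik_profile() -> VaccineProfile:
    for p in load_vaccine_profiles():
        if p.source == "Telegram":
            return p
    raise LookupError("self-report profile not found")
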