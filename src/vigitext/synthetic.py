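"""Synthetic self-report corpus generator.

Emulates the statistical structure of a crowd-sourced vaccine adverse-event
(AE) reporting channel: each message carries a short metadata header
(gender letter, age, dose marker, date) followed by colloquial symptom
mentions.  The generator produces messages *with ground truth*, so every
downstream stage (parsing, classification, statistics, networks) can be
tested end to end without any real data.

Generative model
----------------
Each report has latent covariates: disclosed-or-not gender, age and dose
phase.  The 12 symptom indicators are independent Bernoulli draws (unless a
latent correlation factor is switched on) with per-class probability

    p_c = clip( base_c * g * d * a , 0, 1 )

where ``g`` is the female multiplier for disclosed women, ``d`` the
first-dose multiplier for reports covering a first dose (first or both),
and ``a`` an age factor chosen so that the *expected total AE count of that
report* declines by exactly ``age_slope`` per year of age:

    a = max(0, 1 - age_slope * (age - reference_age) / (E0 * g * d)),

with ``E0`` the sum of base prevalences.  Normalising by the report's own
expected count ``E0*g*d`` (rather than by ``E0`` alone) makes the age
decrement additive and identical across covariate groups, so an ordinary
least-squares fit of AE count on age over the whole corpus recovers
``age_slope`` without attenuation, while at the reference age the
female/male and first/second ratios of mean counts equal the configured
multipliers exactly.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .labels import N_CLASSES, SYMPTOMS, class_index
from .lexicon import DEFAULT_LEXICON, Lexicon


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


class LexiconError(KeyError):
    """A true label has no surface phrase to render."""


#: Default per-class marginal prevalences (probability scale).
DEFAULT_PREVALENCE: Mapping[str, float] = {
    "fever": 0.4743,
    "pain": 0.4657,
    "fatigue": 0.3354,
    "headache": 0.2479,
    "chills": 0.2302,
    "insomnia": 0.0521,
    "lymph_node_enlargement": 0.0162,
    "erythema": 0.0277,
    "swelling": 0.0179,
    "pruritus": 0.0173,
    "nausea_vomiting": 0.0305,
    "diarrhea": 0.0057,
}

#: Systemic-reaction classes raised jointly by the optional latent factor.
SYSTEMIC_FACTOR_CLASSES: tuple[str, ...] = ("fever", "chills", "fatigue", "headache")

_CORPUS_START = _dt.date(2020, 12, 9)
_CORPUS_DAYS = 130


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic corpus.

    Defaults are calibrated to the emulated channel: marginal prevalences
    of the 12 classes, a 2.5/2.1 female/male ratio of mean AE counts, a
    2.2/1.9 first/second-dose ratio, and a decline of 0.0457 AEs per year
    of age.  ``reference_age`` is the age at which the multiplicative
    group effects apply unadjusted; it defaults to the mean of the default
    uniform age range so group ratios of means are preserved corpus-wide.
    """

    n_messages: int = 1000
    base_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    female_multiplier: float = 2.5 / 2.1
    first_dose_multiplier: float = 2.2 / 1.9
    age_slope: float = 0.0457
    reference_age: float = 54.0
    prop_female: float = 3992 / 6754
    prop_with_gender: float = 6754 / 11515
    prop_with_age: float = 6754 / 11515
    prop_with_dose: float = 8474 / 11515
    # (first, second, both) shares among dose-disclosing reports
    dose_distribution: tuple[float, float, float] = (
        4174 / 8474,
        1251 / 8474,
        3049 / 8474,
    )
    age_range: tuple[int, int] = (18, 90)
    # latent correlation factors: ((classes...), strength) pairs
    factors: tuple[tuple[tuple[str, ...], float], ...] = ()
    lexicon: Lexicon = DEFAULT_LEXICON
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_messages < 0:
            raise ConfigurationError("n_messages must be >= 0")
        for name, p in self.base_prevalence.items():
            if name not in SYMPTOMS:
                raise ConfigurationError(f"unknown symptom class {name!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"base_prevalence[{name!r}]={p} not in [0,1]")
        missing = set(SYMPTOMS) - set(self.base_prevalence)
        if missing:
            raise ConfigurationError(f"base_prevalence missing classes: {sorted(missing)}")
        if self.female_multiplier <= 0 or self.first_dose_multiplier <= 0:
            raise ConfigurationError("multipliers must be > 0")
        for attr in ("prop_female", "prop_with_gender", "prop_with_age", "prop_with_dose"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{attr}={v} not in [0,1]")
        if abs(sum(self.dose_distribution) - 1.0) > 1e-9 or min(self.dose_distribution) < 0:
            raise ConfigurationError("dose_distribution must be non-negative and sum to 1")
        lo, hi = self.age_range
        if lo > hi:
            raise ConfigurationError("age_range must be (low, high) with low <= high")
        for classes, strength in self.factors:
            if not 0.0 <= strength < 1.0:
                raise ConfigurationError(f"factor strength {strength} not in [0,1)")
            for cls in classes:
                class_index(cls)

    @property
    def base_vector(self) -> np.ndarray:
        return np.array([self.base_prevalence[c] for c in SYMPTOMS], dtype=float)

    @property
    def expected_base_count(self) -> float:
        """E0: expected AE count at neutral covariates and reference age."""
        return float(self.base_vector.sum())

    def with_systemic_factor(self, strength: float) -> "SyntheticConfig":
        """Copy of the config with the shared systemic-reaction factor on."""
        return replace(self, factors=((SYSTEMIC_FACTOR_CLASSES, strength),))


@dataclass(frozen=True)
class GroundTruthRecord:
    """Ground truth for one synthetic message."""

    message_id: str
    true_labels: np.ndarray  # (12,) bool, canonical order
    gender: str  # female | male | undisclosed
    age: int | None
    dose: str  # first | second | both | undisclosed
    timestamp: _dt.date

    def __post_init__(self) -> None:
        labels = np.asarray(self.true_labels, dtype=bool)
        if labels.shape != (N_CLASSES,):
            raise ValueError("true_labels must have length 12")
        object.__setattr__(self, "true_labels", labels)
        if self.gender not in ("female", "male", "undisclosed"):
            raise ValueError(f"invalid gender {self.gender!r}")
        if self.dose not in ("first", "second", "both", "undisclosed"):
            raise ValueError(f"invalid dose {self.dose!r}")


@dataclass(frozen=True)
class RawMessage:
    """One rendered self-report message."""

    message_id: str
    timestamp: _dt.datetime
    text: str


def effective_probabilities(
    config: SyntheticConfig,
    gender: str,
    dose: str,
    age: int | None,
    factor_states: Sequence[bool] = (),
) -> np.ndarray:
    """Per-class Bernoulli probabilities for a report with given covariates.

    Undisclosed covariates act neutrally (multiplier 1, no age term).
    """
    g = config.female_multiplier if gender == "female" else 1.0
    d = config.first_dose_multiplier if dose in ("first", "both") else 1.0
    if age is None:
        a = 1.0
    else:
        expected = config.expected_base_count * g * d
        a = 1.0 - config.age_slope * (age - config.reference_age) / expected
        a = max(0.0, a)
    p = config.base_vector * g * d * a
    for (classes, strength), z in zip(config.factors, factor_states):
        mult = 1.0 + strength if z else 1.0 - strength
        for cls in classes:
            p[class_index(cls)] *= mult
    return np.clip(p, 0.0, 1.0)


def sample_report(
    config: SyntheticConfig,
    rng: np.random.Generator,
    message_id: str = "msg000000",
    timestamp: _dt.date | None = None,
) -> GroundTruthRecord:
    """Draw one ground-truth record (covariates + 12 symptom indicators)."""
    if timestamp is None:
        timestamp = _CORPUS_START

    if rng.random() < config.prop_with_gender:
        gender = "female" if rng.random() < config.prop_female else "male"
    else:
        gender = "undisclosed"

    age: int | None = None
    lo, hi = config.age_range
    if rng.random() < config.prop_with_age:
        age = int(rng.integers(lo, hi + 1))

    if rng.random() < config.prop_with_dose:
        dose = ("first", "second", "both")[
            int(rng.choice(3, p=np.asarray(config.dose_distribution)))
        ]
    else:
        dose = "undisclosed"

    factor_states = [bool(rng.random() < 0.5) for _ in config.factors]
    p = effective_probabilities(config, gender, dose, age, factor_states)
    labels = rng.random(N_CLASSES) < p
    return GroundTruthRecord(
        message_id=message_id,
        true_labels=labels,
        gender=gender,
        age=age,
        dose=dose,
        timestamp=timestamp,
    )


def _age_phrase(age: int) -> str:
    # Russian numeral agreement: 21 год, 22-24 года, 25..30 лет, ...
    if age % 100 in (11, 12, 13, 14):
        word = "лет"
    elif age % 10 == 1:
        word = "год"
    elif age % 10 in (2, 3, 4):
        word = "года"
    else:
        word = "лет"
    return f"{age} {word}"


def _fmt_date(d: _dt.date) -> str:
    return d.strftime("%d.%m.%y")


def render_message(
    record: GroundTruthRecord,
    lexicon: Lexicon | None = None,
    rng: np.random.Generator | None = None,
    n_decoys: int | None = None,
) -> str:
    """Render a record as message text with the channel's header convention.

    Header: gender letter, "NN лет/года/год", dose marker(s) "V1"/"V2" with
    a dd.mm.yy date — for disclosed fields only.  Body: exactly one phrase
    per true symptom (uniform choice) plus 0-2 decoy phrases.  The header is
    round-trippable: :func:`vigitext.parsing.parse_metadata` recovers every
    disclosed field.
    """
    if lexicon is None:
        lexicon = DEFAULT_LEXICON
    if rng is None:
        rng = np.random.default_rng(0)

    phrases: list[str] = []
    for cls, flag in zip(SYMPTOMS, record.true_labels):
        if not flag:
            continue
        if cls not in lexicon.phrases or not lexicon.phrases[cls]:
            raise LexiconError(f"no lexicon phrase for true label {cls!r}")
        options = lexicon.phrases[cls]
        phrases.append(options[int(rng.integers(len(options)))])

    if n_decoys is None:
        n_decoys = int(rng.integers(0, 3))
    n_decoys = min(n_decoys, len(lexicon.decoys))
    if n_decoys:
        picks = rng.choice(len(lexicon.decoys), size=n_decoys, replace=False)
        phrases.extend(lexicon.decoys[i] for i in picks)
    order = rng.permutation(len(phrases))
    phrases = [phrases[i] for i in order]
    body = ", ".join(phrases)

    head_bits = []
    if record.gender == "male":
        head_bits.append("М")
    elif record.gender == "female":
        head_bits.append("Ж")
    if record.age is not None:
        head_bits.append(_age_phrase(record.age))
    header = ", ".join(head_bits)

    date1 = _fmt_date(record.timestamp)
    date2 = _fmt_date(record.timestamp + _dt.timedelta(days=21))
    parts: list[str] = []
    if header:
        parts.append(header + ".")
    if record.dose == "first":
        parts.append(f"V1 {date1}" + (f" {body}." if body else "."))
    elif record.dose == "second":
        parts.append(f"V2 {date1}" + (f" {body}." if body else "."))
    elif record.dose == "both":
        parts.append(f"V1 {date1}" + (f" {body}." if body else "."))
        parts.append(f"V2 {date2} то же самое.")
    else:
        if body:
            parts.append(body + ".")
    return " ".join(parts).strip()


def _sample_days(rng: np.random.Generator, n: int) -> np.ndarray:
    """Rise-then-decay daily-volume curve (gamma-shaped weights)."""
    days = np.arange(_CORPUS_DAYS, dtype=float)
    shape, scale = 4.0, 22.0
    w = np.power(days + 1.0, shape - 1.0) * np.exp(-(days + 1.0) / scale)
    w /= w.sum()
    return rng.choice(_CORPUS_DAYS, size=n, p=w)


def generate_corpus(
    config: SyntheticConfig,
) -> tuple[list[RawMessage], list[GroundTruthRecord]]:
    """Generate ``config.n_messages`` (message, ground truth) pairs.

    Deterministic: the same config (including seed) yields a byte-identical
    corpus.
    """
    rng = np.random.default_rng(config.seed)
    config.lexicon.validate()
    n = config.n_messages
    days = _sample_days(rng, n) if n else np.array([], dtype=int)
    messages: list[RawMessage] = []
    records: list[GroundTruthRecord] = []
    for i in range(n):
        day = int(days[i])
        date = _CORPUS_START + _dt.timedelta(days=day)
        msg_id = f"msg{i:06d}"
        rec = sample_report(config, rng, message_id=msg_id, timestamp=date)
        text = render_message(rec, config.lexicon, rng)
        seconds = int(rng.integers(0, 86400))
        ts = _dt.datetime.combine(date, _dt.time()) + _dt.timedelta(seconds=seconds)
        messages.append(RawMessage(message_id=msg_id, timestamp=ts, text=text))
        records.append(rec)
    return messages, records


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_corpus_jsonl(
    messages: Sequence[RawMessage], path: str | Path, seed: int | None = None
) -> None:
    """Write messages as JSONL (id, ISO-8601 timestamp, text), UTF-8.

    The seed is recorded in a leading ``#`` comment line.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        for m in messages:
            fh.write(
                json.dumps(
                    {
                        "id": m.message_id,
                        "timestamp": m.timestamp.isoformat(),
                        "text": m.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_corpus_jsonl(path: str | Path) -> list[RawMessage]:
    """Read a JSONL message file; ``#`` comment lines are skipped."""
    messages = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            obj = json.loads(line)
            messages.append(
                RawMessage(
                    message_id=str(obj["id"]),
                    timestamp=_dt.datetime.fromisoformat(obj["timestamp"]),
                    text=obj["text"],
                )
            )
    return messages


def ground_truth_frame(records: Sequence[GroundTruthRecord]) -> pd.DataFrame:
    """Tabular view of ground truth (one row per message)."""
    rows = []
    for r in records:
        row = {
            "message_id": r.message_id,
            "gender": r.gender,
            "age": r.age if r.age is not None else pd.NA,
            "dose": r.dose,
            "timestamp": r.timestamp.isoformat(),
        }
        for cls, flag in zip(SYMPTOMS, r.true_labels):
            row[cls] = bool(flag)
        rows.append(row)
    cols = ["message_id", "gender", "age", "dose", "timestamp", *SYMPTOMS]
    return pd.DataFrame(rows, columns=cols)


def write_ground_truth(records: Sequence[GroundTruthRecord], path: str | Path) -> None:
    ground_truth_frame(records).to_csv(path, index=False)


def config_from_toml(path: str | Path) -> SyntheticConfig:
    """Load a generator configuration from a TOML key-value file.

    Unknown keys are rejected; ``base_prevalence`` may be given as a table
    overriding individual classes.
    """
    with Path(path).open("rb") as fh:
        raw = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    if "base_prevalence" in raw:
        prev = dict(DEFAULT_PREVALENCE)
        prev.update(raw["base_prevalence"])
        raw["base_prevalence"] = prev
    if "dose_distribution" in raw:
        raw["dose_distribution"] = tuple(raw["dose_distribution"])
    if "age_range" in raw:
        raw["age_range"] = tuple(raw["age_range"])
    if "factors" in raw:
        raw["factors"] = tuple(
            (tuple(classes), float(strength)) for classes, strength in raw["factors"]
        )
    return SyntheticConfig(**raw)
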