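"""Inter-vaccine reactogenicity profile comparison.

A vaccine's mild-AE profile is the vector of reported frequencies of six
reasonably comparable symptoms (pain, headache, fatigue, fever, chills,
nausea) on the percent scale.  Profiles from different registries are
compared by Euclidean distance (in percentage-point units), aggregated
into platform-group distances (vector vs mRNA), and hierarchically
clustered.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

#: Canonical symptom order of a profile.
PROFILE_SYMPTOMS: tuple[str, ...] = (
    "pain",
    "headache",
    "fatigue",
    "fever",
    "chills",
    "nausea",
)

PLATFORMS = ("vector", "mRNA", "other")


@dataclass(frozen=True)
class VaccineProfile:
    """Six-symptom percentage vector from a named source registry."""

    vaccine: str
    source: str
    platform: str
    frequencies: np.ndarray  # (6,) percent scale

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        if freqs.shape != (len(PROFILE_SYMPTOMS),):
            raise ValueError("profile needs exactly 6 frequencies")
        if np.isnan(freqs).any():
            raise ValueError(f"profile {self.vaccine!r} has missing entries")
        if freqs.min() < 0 or freqs.max() > 100:
            raise ValueError("frequencies must be percentages in [0, 100]")
        if self.platform not in PLATFORMS:
            raise ValueError(f"platform must be one of {PLATFORMS}")
        object.__setattr__(self, "frequencies", freqs)

    @property
    def name(self) -> str:
        return f"{self.vaccine} ({self.source})"


def euclidean_distance(p: VaccineProfile, q: VaccineProfile) -> float:
    """Euclidean distance between two profiles, in percentage points."""
    return float(np.linalg.norm(p.frequencies - q.frequencies))


def distance_matrix(profiles: Sequence[VaccineProfile]) -> pd.DataFrame:
    """Symmetric pairwise distance matrix (zero diagonal), names as labels."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError("duplicate profile names")
    mat = np.zeros((len(profiles), len(profiles)))
    for i, p in enumerate(profiles):
        for j, q in enumerate(profiles):
            if i < j:
                mat[i, j] = mat[j, i] = euclidean_distance(p, q)
    return pd.DataFrame(mat, index=names, columns=names)


def group_distance(
    profile: VaccineProfile,
    group: Sequence[VaccineProfile],
    aggregate: str = "sum",
) -> float:
    """Aggregate distance from one profile to a group of profiles.

    ``aggregate`` is ``"sum"`` or ``"mean"`` of the pairwise distances.
    """
    if not group:
        raise ValueError("group must be nonempty")
    dists = [euclidean_distance(profile, q) for q in group]
    if aggregate == "sum":
        return float(np.sum(dists))
    if aggregate == "mean":
        return float(np.mean(dists))
    raise ValueError(f"aggregate must be 'sum' or 'mean', got {aggregate!r}")


def platform_distances(
    profile: VaccineProfile,
    profiles: Sequence[VaccineProfile],
    aggregate: str = "sum",
) -> dict[str, float]:
    """Aggregate distance from ``profile`` to each platform group.

    The profile itself is excluded from its own platform's group.
    """
    out = {}
    for platform in ("vector", "mRNA"):
        group = [
            q for q in profiles if q.platform == platform and q.name != profile.name
        ]
        if group:
            out[platform] = group_distance(profile, group, aggregate=aggregate)
    return out


def cluster_profiles(matrix: pd.DataFrame, method: str = "average") -> np.ndarray:
    """Agglomerative clustering of a profile distance matrix.

    Returns a scipy linkage matrix (ordered merges with heights).  The
    matrix must be symmetric with zero diagonal.
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(arr), 0.0):
        raise ValueError("distance matrix must have zero diagonal")
    return linkage(squareform(arr, checks=False), method=method)


def nearest_profile(profile: VaccineProfile, others: Sequence[VaccineProfile]) -> VaccineProfile:
    """The single closest other profile by Euclidean distance."""
    candidates = [q for q in others if q.name != profile.name]
    if not candidates:
        raise ValueError("no other profiles")
    return min(candidates, key=lambda q: euclidean_distance(profile, q))


def load_profiles(path: str | Path) -> list[VaccineProfile]:
    """Load profiles from CSV (vaccine, source, platform, 6 symptom columns).

    Profiles with missing entries are rejected.
    """
    df = pd.read_csv(path, comment="#")
    required = {"vaccine", "source", "platform", *PROFILE_SYMPTOMS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV missing columns: {sorted(missing)}")
    profiles = []
    for _, row in df.iterrows():
        profiles.append(
            VaccineProfile(
                vaccine=str(row["vaccine"]),
                source=str(row["source"]),
                platform=str(row["platform"]),
                frequencies=np.array([row[s] for s in PROFILE_SYMPTOMS], dtype=float),
            )
        )
    return profiles
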