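"""Canonical adverse-event taxonomy.

Twelve mild adverse-event (AE) classes for short vaccine self-reports,
grouped the way reactogenicity studies group them: systemic (whole-body),
local (injection-site) and gastric (gastrointestinal) reactions.  The order
of :data:`SYMPTOMS` is canonical across the whole package: every label
vector, frequency table and co-occurrence matrix uses it.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

#: Canonical class order.  Immutable; do not reorder.
SYMPTOMS: tuple[str, ...] = (
    "fever",
    "pain",
    "fatigue",
    "headache",
    "chills",
    "insomnia",
    "lymph_node_enlargement",
    "erythema",
    "swelling",
    "pruritus",
    "nausea_vomiting",
    "diarrhea",
)

N_CLASSES: int = len(SYMPTOMS)

#: Reactogenicity groups (systemic / local / gastric).
SYMPTOM_GROUPS: Mapping[str, tuple[str, ...]] = {
    "systemic": (
        "fever",
        "pain",
        "fatigue",
        "headache",
        "chills",
        "insomnia",
        "lymph_node_enlargement",
    ),
    "local": ("erythema", "swelling", "pruritus"),
    "gastric": ("nausea_vomiting", "diarrhea"),
}

_INDEX: Mapping[str, int] = {name: i for i, name in enumerate(SYMPTOMS)}


def class_index(name: str) -> int:
    """Index of a symptom class in the canonical order."""
    try:
        return _INDEX[name]
    except KeyError:
        raise KeyError(f"unknown symptom class: {name!r}") from None


def label_vector(positives: Iterable[str] = ()) -> np.ndarray:
    """Boolean label vector (length 12) with the named classes set true."""
    vec = np.zeros(N_CLASSES, dtype=bool)
    for name in positives:
        vec[class_index(name)] = True
    return vec


def labels_to_names(labels: Sequence[bool] | np.ndarray) -> tuple[str, ...]:
    """Names of the classes set true in a label vector."""
    arr = np.asarray(labels, dtype=bool)
    if arr.shape != (N_CLASSES,):
        raise ValueError(f"label vector must have length {N_CLASSES}, got shape {arr.shape}")
    return tuple(name for name, flag in zip(SYMPTOMS, arr) if flag)


def stack_labels(labelsets: Sequence[Sequence[bool]]) -> np.ndarray:
    """Stack label sets into an (n, 12) boolean matrix, validating width."""
    if len(labelsets) == 0:
        return np.zeros((0, N_CLASSES), dtype=bool)
    mat = np.asarray(labelsets, dtype=bool)
    if mat.ndim != 2 or mat.shape[1] != N_CLASSES:
        raise ValueError(f"expected (n, {N_CLASSES}) label matrix, got shape {mat.shape}")
    return mat
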