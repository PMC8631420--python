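"""Metadata extraction and sentence splitting for self-report messages.

Reporters in the emulated channel follow a loose header convention
("М, 33 года. V1 24.01.21 ..."), so gender, age and dose phase are
recovered by counting gender-letter abbreviations and regular-expression
matching.  Parsing is *total*: it never raises on arbitrary text; any field
whose pattern is absent (or ambiguous) is reported as undisclosed.

Token lists are configurable because colloquial conventions drift; the
defaults cover Cyrillic and common Latin variants.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

#: Age accepted only within these bounds (parsing policy; downstream
#: analyses may filter further, e.g. to adults only).
AGE_BOUNDS = (10, 110)

# Gender letters: Cyrillic М/Ж and Latin M/F, case-insensitive, word-bounded.
_MALE_RE = re.compile(r"(?<!\w)[МM](?!\w)", re.IGNORECASE | re.UNICODE)
_FEMALE_RE = re.compile(r"(?<!\w)[ЖF](?!\w)", re.IGNORECASE | re.UNICODE)

# Age: integer adjacent to an age keyword ("33 года", "45 лет", "21 год",
# "33 y.o.").  The number must immediately precede the keyword.
_AGE_RE = re.compile(
    r"(?<![\d.])(\d{1,3})\s*(?:год(?:а|у)?\b|лет\b|y\.?\s?o\.?)",
    re.IGNORECASE | re.UNICODE,
)

# Dose markers: V1/V2, Cyrillic В1/В2, and spelled-out ordinals.
_FIRST_RE = re.compile(r"(?<!\w)(?:[VВ]\s?1|перв(?:ая|ой|ый))(?!\w)", re.IGNORECASE)
_SECOND_RE = re.compile(r"(?<!\w)(?:[VВ]\s?2|втор(?:ая|ой|ую))(?!\w)", re.IGNORECASE)

# Sentence-final punctuation followed by whitespace.  Dots inside dates
# (24.01.21) and decimals (38.5) are not followed by whitespace, so they
# never split.
_SENT_RE = re.compile(r"(?<=[.!?…])\s+")


@dataclass(frozen=True)
class ParsedReport:
    """Metadata extracted from one message."""

    message_id: str
    gender: str  # female | male | undisclosed
    age: int | None
    dose: str  # first | second | both | undisclosed
    sentences: tuple[str, ...] = field(default_factory=tuple)


def parse_metadata(text: str, message_id: str = "") -> ParsedReport:
    """Extract gender, age and dose phase from message text.

    Rules: first gender letter wins, but conflicting letters (both М and Ж
    present) yield undisclosed; the first in-range integer adjacent to an
    age keyword is the age; dose is first/second/both according to which
    dose markers match.  Absent patterns give undisclosed/absent fields.
    """
    if not isinstance(text, str):
        text = "" if text is None else str(text)

    male = bool(_MALE_RE.search(text))
    female = bool(_FEMALE_RE.search(text))
    if male and female:
        gender = "undisclosed"
    elif male:
        gender = "male"
    elif female:
        gender = "female"
    else:
        gender = "undisclosed"

    age: int | None = None
    for m in _AGE_RE.finditer(text):
        value = int(m.group(1))
        if AGE_BOUNDS[0] <= value <= AGE_BOUNDS[1]:
            age = value
            break

    first = bool(_FIRST_RE.search(text))
    second = bool(_SECOND_RE.search(text))
    if first and second:
        dose = "both"
    elif first:
        dose = "first"
    elif second:
        dose = "second"
    else:
        dose = "undisclosed"

    return ParsedReport(
        message_id=message_id,
        gender=gender,
        age=age,
        dose=dose,
        sentences=tuple(split_sentences(text)),
    )


def split_sentences(text: str) -> list[str]:
    """Split text on sentence-final punctuation followed by whitespace.

    Dotted dates and decimal numbers are protected (their dots are not
    followed by whitespace).  Returns no empty spans; text without terminal
    punctuation comes back as a single span.
    """
    if not text or not text.strip():
        return []
    spans = [s.strip() for s in _SENT_RE.split(text)]
    return [s for s in spans if s]


def parse_corpus(
    messages: Sequence, id_attr: str = "message_id", text_attr: str = "text"
) -> list[ParsedReport]:
    """Parse a sequence of message objects (e.g. ``RawMessage``)."""
    return [
        parse_metadata(getattr(m, text_attr), message_id=getattr(m, id_attr))
        for m in messages
    ]


def parsed_frame(reports: Sequence[ParsedReport]) -> pd.DataFrame:
    """Tabular view of parsed metadata."""
    return pd.DataFrame(
        {
            "message_id": [r.message_id for r in reports],
            "gender": [r.gender for r in reports],
            "age": [r.age if r.age is not None else pd.NA for r in reports],
            "dose": [r.dose for r in reports],
            "n_sentences": [len(r.sentences) for r in reports],
        }
    )


def write_parsed_csv(reports: Sequence[ParsedReport], path: str | Path) -> None:
    parsed_frame(reports).to_csv(path, index=False)
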