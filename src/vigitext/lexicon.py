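"""Surface-form lexicon for rendering and recognising symptom mentions.

Self-reports in the emulated community are colloquial Russian, so the
default lexicon is Cyrillic; a transliterated (Latin) variant is shipped so
the pipeline can be exercised with either script — everything downstream is
UTF-8 and encoding-agnostic.  Phrases are unique to their class, which is
what makes a rendered corpus linearly separable for the classifier tests.

Decoy phrases are realistic non-symptom content (the 12-class taxonomy does
not cover, e.g., nasal congestion) mixed into message bodies so that
classification is not trivially "any text implies a label".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .labels import SYMPTOMS


@dataclass(frozen=True)
class Lexicon:
    """Phrases per symptom class plus decoy (non-symptom) phrases."""

    phrases: Mapping[str, tuple[str, ...]]
    decoys: tuple[str, ...] = ()

    def validate(self) -> None:
        for cls in SYMPTOMS:
            if cls not in self.phrases or len(self.phrases[cls]) == 0:
                raise ValueError(f"lexicon has no phrases for class {cls!r}")

    def phrases_for(self, cls: str) -> tuple[str, ...]:
        return tuple(self.phrases[cls])


DEFAULT_LEXICON = Lexicon(
    phrases={
        "fever": ("температура 38", "темп 39", "жар", "поднялась температура"),
        "pain": ("боль в руке", "ломота в мышцах", "болело плечо", "ныла рука"),
        "fatigue": ("слабость", "усталость", "разбитость"),
        "headache": ("болит голова", "голова раскалывается"),
        "chills": ("озноб", "знобит", "морозит"),
        "insomnia": ("бессонница", "плохо спал ночью", "не удалось уснуть"),
        "lymph_node_enlargement": ("увеличились лимфоузлы", "воспалился лимфоузел"),
        "erythema": ("покраснение в месте укола", "краснота на плече"),
        "swelling": ("отек руки", "припухлость в месте инъекции"),
        "pruritus": ("зуд в месте укола", "чешется рука"),
        "nausea_vomiting": ("тошнота", "тошнило", "рвота"),
        "diarrhea": ("диарея", "жидкий стул", "расстройство желудка"),
    },
    decoys=(
        "заложенность носа",
        "через 12 часов",
        "на следующий день",
        "настроение хорошее",
        "аппетит обычный",
    ),
)

TRANSLIT_LEXICON = Lexicon(
    phrases={
        "fever": ("temperatura 38", "temp 39", "zhar", "podnyalas temperatura"),
        "pain": ("bol v ruke", "lomota v myshtsakh", "bolelo plecho"),
        "fatigue": ("slabost", "ustalost", "razbitost"),
        "headache": ("bolit golova", "golova raskalyvaetsya"),
        "chills": ("oznob", "znobit", "morozit"),
        "insomnia": ("bessonnitsa", "plokho spal nochyu"),
        "lymph_node_enlargement": ("uvelichilis limfouzly", "vospalilsya limfouzel"),
        "erythema": ("pokrasnenie v meste ukola", "krasnota na pleche"),
        "swelling": ("otek ruki", "pripukhlost v meste inektsii"),
        "pruritus": ("zud v meste ukola", "cheshetsya ruka"),
        "nausea_vomiting": ("toshnota", "toshnilo", "rvota"),
        "diarrhea": ("diareya", "zhidkiy stul", "rasstroystvo zheludka"),
    },
    decoys=(
        "zalozhennost nosa",
        "cherez 12 chasov",
        "na sleduyushchiy den",
        "nastroenie khoroshee",
    ),
)
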