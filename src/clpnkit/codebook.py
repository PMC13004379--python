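"""The 32-item Self-Report Symptom Scale (SRSS) codebook.

The instrument covers 19 physical, 5 cognitive and 8 psychological symptoms.
Each item is scored on three dimensions — frequency (1-4), severity (1-4) and
distress (1-5) — whose sum is the per-symptom "total experience score"
(0 when the symptom is absent, otherwise 3-13). The domain partition
(physical / cognitive / psychological) doubles as the community structure
used for bridge centrality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .errors import ValidationError

PHYSICAL = "physical"
COGNITIVE = "cognitive"
PSYCHOLOGICAL = "psychological"
DOMAINS = (PHYSICAL, COGNITIVE, PSYCHOLOGICAL)

_ENTRIES: tuple[tuple[str, str, str], ...] = (
    ("PHYS1", "Fatigue", PHYSICAL),
    ("PHYS2", "Dizziness", PHYSICAL),
    ("PHYS3", "Headache", PHYSICAL),
    ("PHYS4", "Fever", PHYSICAL),
    ("PHYS5", "Cough", PHYSICAL),
    ("PHYS6", "Sleep disturbance", PHYSICAL),
    ("PHYS7", "Vision blur", PHYSICAL),
    ("PHYS8", "Rash", PHYSICAL),
    ("PHYS9", "Mouth ulcer", PHYSICAL),
    ("PHYS10", "Muscle/joint ache", PHYSICAL),
    ("PHYS11", "Hand/foot pain", PHYSICAL),
    ("PHYS12", "Appetite loss", PHYSICAL),
    ("PHYS13", "Bloating/abdominal pain/diarrhea", PHYSICAL),
    ("PHYS14", "Nausea/vomit", PHYSICAL),
    ("PHYS15", "Lipodystrophy", PHYSICAL),
    ("PHYS16", "Weight loss", PHYSICAL),
    ("PHYS17", "Low sex drive", PHYSICAL),
    ("PHYS18", "Hair loss", PHYSICAL),
    ("PHYS19", "Shortness of breath", PHYSICAL),
    ("COGS1", "Having difficulty in concentrating", COGNITIVE),
    ("COGS2", "Slow react", COGNITIVE),
    ("COGS3", "Memory loss", COGNITIVE),
    ("COGS4", "Having difficulty in reasoning", COGNITIVE),
    ("COGS5", "Becoming confusing", COGNITIVE),
    ("PSYS1", "Feeling fearful", PSYCHOLOGICAL),
    ("PSYS2", "Hardly focusing on anything", PSYCHOLOGICAL),
    ("PSYS3", "Worry overwhelmed me", PSYCHOLOGICAL),
    ("PSYS4", "Feeling uneasy", PSYCHOLOGICAL),
    ("PSYS5", "Feeling worthless", PSYCHOLOGICAL),
    ("PSYS6", "Feeling helpless", PSYCHOLOGICAL),
    ("PSYS7", "Feeling downhearted", PSYCHOLOGICAL),
    ("PSYS8", "Feeling hopeless", PSYCHOLOGICAL),
)


@dataclass(frozen=True)
class Symptom:
    code: str
    label: str
    domain: str


class Codebook:
    """Ordered, immutable collection of the 32 SRSS symptoms."""

    def __init__(self, entries: tuple[Symptom, ...]):
        codes = [e.code for e in entries]
        if len(set(codes)) != len(codes):
            raise ValidationError("symptom codes must be unique")
        self._entries = entries
        self._by_code = {e.code: e for e in entries}

    @property
    def entries(self) -> tuple[Symptom, ...]:
        return self._entries

    @property
    def codes(self) -> list[str]:
        return [e.code for e in self._entries]

    def lookup(self, code: str) -> Symptom:
        try:
            return self._by_code[code]
        except KeyError:
            raise KeyError(f"unknown symptom code: {code!r}") from None

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[Symptom]:
        return iter(self._entries)

    def domain_of(self, code: str) -> str:
        return self.lookup(code).domain

    def partition(self) -> dict[str, str]:
        """Community partition mapping every code to its symptom domain."""
        return {e.code: e.domain for e in self._entries}

    def codes_in_domain(self, domain: str) -> list[str]:
        return [e.code for e in self._entries if e.domain == domain]


def load_codebook() -> Codebook:
    """The canonical 32-symptom SRSS codebook (PHYS1...PSYS8, fixed order)."""
    return Codebook(tuple(Symptom(*e) for e in _ENTRIES))
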