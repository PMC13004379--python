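"""SRSS item scoring and per-wave endorsement summaries.

Each symptom is rated on frequency (1-4), severity (1-4) and distress (1-5);
the total experience score is their sum, or 0 when the symptom was not
experienced. All three Likert scales are 1-based, so the smallest total a
present symptom can take is 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .codebook import Codebook, load_codebook
from .errors import SchemaError, ValidationError
from .panel import TwoWavePanel


@dataclass(frozen=True)
class ItemResponse:
    """One participant's response to one symptom item.

    Dimension scores are carried only when the symptom is present.
    """

    present: bool
    frequency: int | None = None
    severity: int | None = None
    distress: int | None = None

    def __post_init__(self):
        if not self.present:
            if any(v is not None for v in (self.frequency, self.severity, self.distress)):
                raise ValidationError("absent symptom must not carry dimension scores")
            return
        for name, value, hi in (("frequency", self.frequency, 4),
                                ("severity", self.severity, 4),
                                ("distress", self.distress, 5)):
            if value is None:
                raise ValidationError(f"present symptom requires a {name} score")
            if not (1 <= value <= hi):
                raise ValidationError(f"{name}={value} outside Likert range 1-{hi}")


def score_item(response: ItemResponse) -> int:
    """Total experience score: 0 when absent, else frequency+severity+distress."""
    if not response.present:
        return 0
    return int(response.frequency + response.severity + response.distress)


def score_wave(responses: Mapping[str, ItemResponse],
               codebook: Codebook | None = None) -> pd.Series:
    """Score a full wave of item responses into a 32-entry total-score vector."""
    codebook = codebook or load_codebook()
    missing = [c for c in codebook.codes if c not in responses]
    if missing:
        raise ValidationError(f"missing responses for codes: {missing}")
    return pd.Series({c: score_item(responses[c]) for c in codebook.codes},
                     name="total_score")


def endorsement_counts(panel: TwoWavePanel, wave: str) -> pd.Series:
    """Per-symptom count of participants with a nonzero score at ``wave``.

    T2 counts are restricted to completers (non-completers have no T2 data).
    """
    if wave == "T2":
        panel = panel.completers()
    if len(panel) == 0:
        warnings.warn("endorsement_counts on an empty panel", stacklevel=2)
        return pd.Series(0, index=panel.codebook.codes, dtype=int)
    scores = panel.scores(wave)
    return (scores > 0).sum(axis=0).astype(int)


_LONG_COLUMNS = ("participant_id", "wave", "code", "present",
                 "frequency", "severity", "distress")


def score_long_table(items: pd.DataFrame, codebook: Codebook | None = None) -> pd.DataFrame:
    """Score a long-form item table into wide per-wave total-score columns.

    Expects one row per (participant, wave, symptom) with columns
    ``participant_id, wave, code, present, frequency, severity, distress``;
    dimension cells may be empty when ``present`` is false. Returns a wide
    frame with ``<CODE>_T1`` / ``<CODE>_T2`` total-score columns.
    """
    codebook = codebook or load_codebook()
    missing = [c for c in _LONG_COLUMNS if c not in items.columns]
    if missing:
        raise SchemaError(f"long item table missing columns: {missing}")

    def _one(row) -> int:
        if not bool(row["present"]):
            return 0
        return score_item(ItemResponse(
            True, int(row["frequency"]), int(row["severity"]), int(row["distress"])))

    records: dict = {}
    for (pid, wave), grp in items.groupby(["participant_id", "wave"], sort=False):
        responses = {}
        for _, row in grp.iterrows():
            if row["code"] not in codebook:
                raise ValidationError(f"unknown symptom code {row['code']!r}")
            responses[row["code"]] = _one(row)
        absent = [c for c in codebook.codes if c not in responses]
        if absent:
            raise ValidationError(
                f"participant {pid} wave {wave}: missing codes {absent}")
        rec = records.setdefault(pid, {"participant_id": pid})
        for code, total in responses.items():
            rec[f"{code}_{wave}"] = total
    return pd.DataFrame(list(records.values()))


def read_item_responses(path: str | Path) -> pd.DataFrame:
    """Read a long-form item-level CSV (see :func:`score_long_table`)."""
    return pd.read_csv(path)
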