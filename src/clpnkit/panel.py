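"""Two-wave symptom panels: validation, container, and CSV round-trip.

A panel is wide-format: one row per participant with an identifier, age in
years, sex (0 = male, 1 = female), a completer flag, one ``<CODE>_T1``
column per symptom, and one ``<CODE>_T2`` column per symptom. T2 cells are
empty for non-completers (participants lost to follow-up between waves).
Valid total experience scores are 0 (symptom absent) or integers in
[3, 13] (frequency 1-4 + severity 1-4 + distress 1-5). Extra covariate
columns (e.g. severity proxies used by the attrition analysis) are carried
through untouched.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .codebook import Codebook, load_codebook
from .errors import SchemaError, ValidationError

REQUIRED_COLUMNS = ("participant_id", "age", "sex", "completer")

_SEX_MAP = {"male": 0, "female": 1, "m": 0, "f": 1, "0": 0, "1": 1, 0: 0, 1: 1}


def _valid_scores(values: np.ndarray) -> np.ndarray:
    """Boolean mask of entries in {0} | [3, 13] (integer-valued)."""
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v) & (v == np.round(v)) & ((v == 0) | ((v >= 3) & (v <= 13)))
    return ok


class TwoWavePanel:
    """Participants x symptoms x {T1, T2} total experience scores."""

    def __init__(self, data: pd.DataFrame, codebook: Codebook | None = None,
                 validate: bool = True):
        self.codebook = codebook or load_codebook()
        self.data = data.reset_index(drop=True)
        if validate:
            self._validate()

    # -- construction / validation --------------------------------------
    def _validate(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        codes = self.codebook.codes
        missing += [f"{c}_T1" for c in codes if f"{c}_T1" not in df.columns]
        missing += [f"{c}_T2" for c in codes if f"{c}_T2" not in df.columns]
        if missing:
            raise SchemaError(f"panel is missing required columns: {missing}")
        if df["participant_id"].duplicated().any():
            dupes = df.loc[df["participant_id"].duplicated(), "participant_id"].tolist()
            raise ValidationError(f"duplicate participant ids: {dupes}")

        bad_cells: list[str] = []
        completer = df["completer"].astype(bool).to_numpy()
        for code in codes:
            t1 = df[f"{code}_T1"].to_numpy(dtype=float)
            ok = _valid_scores(t1)
            for idx in np.flatnonzero(~ok):
                bad_cells.append(f"{df['participant_id'].iloc[idx]}:{code}_T1={t1[idx]}")
            t2 = df[f"{code}_T2"].to_numpy(dtype=float)
            # completers need valid T2 scores; non-completers must have none
            ok2 = _valid_scores(t2)
            for idx in np.flatnonzero(completer & ~ok2):
                bad_cells.append(f"{df['participant_id'].iloc[idx]}:{code}_T2={t2[idx]}")
            for idx in np.flatnonzero(~completer & ~np.isnan(t2)):
                bad_cells.append(
                    f"{df['participant_id'].iloc[idx]}:{code}_T2 present for non-completer"
                )
        if bad_cells:
            shown = ", ".join(bad_cells[:10])
            more = f" (+{len(bad_cells) - 10} more)" if len(bad_cells) > 10 else ""
            raise ValidationError(f"invalid score cells: {shown}{more}")

    # -- accessors -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_completers(self) -> int:
        return int(self.data["completer"].astype(bool).sum())

    @property
    def completer_mask(self) -> np.ndarray:
        return self.data["completer"].astype(bool).to_numpy()

    def completers(self) -> "TwoWavePanel":
        sub = self.data.loc[self.completer_mask].reset_index(drop=True)
        return TwoWavePanel(sub, self.codebook, validate=False)

    def scores(self, wave: str) -> pd.DataFrame:
        """n x 32 score matrix for ``wave`` in {"T1", "T2"} (codebook order)."""
        if wave not in ("T1", "T2"):
            raise ValueError("wave must be 'T1' or 'T2'")
        cols = [f"{c}_{wave}" for c in self.codebook.codes]
        out = self.data[cols].astype(float)
        out.columns = self.codebook.codes
        return out

    def covariates(self, names: tuple[str, ...] = ("age", "sex")) -> pd.DataFrame:
        missing = [c for c in names if c not in self.data.columns]
        if missing:
            raise SchemaError(f"covariates not in panel: {missing}")
        return self.data[list(names)].astype(float)

    @property
    def retention_rate(self) -> float:
        return self.n_completers / self.n


def infer_codebook(columns) -> Codebook:
    """Codebook implied by a panel's ``<CODE>_T1`` columns.

    Falls back from the canonical 32-symptom codebook to a reduced or
    generic one (as produced by the simulator at ``n_nodes != 32``) so that
    reduced panels round-trip through CSV.
    """
    from .codebook import Symptom  # local: avoid importing names not needed above

    canonical = load_codebook()
    codes = [c[:-3] for c in columns if c.endswith("_T1")]
    if codes == canonical.codes:
        return canonical
    entries = []
    known = {s.code: s for s in canonical}
    k = len(codes)
    cuts = (k * 3 // 5, k * 4 // 5)
    for i, code in enumerate(codes):
        if code in known:
            entries.append(known[code])
        else:
            domain = ("physical" if i < cuts[0]
                      else "cognitive" if i < cuts[1] else "psychological")
            entries.append(Symptom(code, code, domain))
    return Codebook(tuple(entries))


def read_panel(path: str | Path, codebook: Codebook | None = None) -> TwoWavePanel:
    """Read and validate a wide-format panel CSV."""
    df = pd.read_csv(path)
    if "sex" in df.columns:
        df["sex"] = df["sex"].map(lambda s: _SEX_MAP.get(
            s.strip().lower() if isinstance(s, str) else s, s))
    return TwoWavePanel(df, codebook or infer_codebook(df.columns))


def write_panel(panel: TwoWavePanel, path: str | Path) -> Path:
    """Write a panel to CSV; non-completer T2 cells are left empty."""
    path = Path(path)
    df = panel.data.copy()
    # keep integer presentation for score columns despite NaN-bearing floats
    for code in panel.codebook.codes:
        for wave in ("T1", "T2"):
            col = f"{code}_{wave}"
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, index=False)
    return path
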