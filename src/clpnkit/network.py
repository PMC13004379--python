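"""Directed weighted symptom networks on the odds-ratio scale.

An :class:`EdgeMatrix` holds the T1 -> T2 adjacency matrix of a cross-lagged
panel network: rows are predictors (symptoms at T1), columns are outcomes
(symptoms at T2), the diagonal holds autoregressive edges and every other
cell a cross-lagged edge. On the odds-ratio scale a weight of exactly 1
means "no edge" (a LASSO-shrunk zero coefficient); weights above 1 are
positive lagged associations, weights below 1 negative ones.

The published adjacency matrix of the source study ships as a package
fixture. As printed it has 32 predictor rows but only 31 outcome columns
(the PSYS7 column is absent from the print); the fixture preserves that
asymmetry rather than inventing a column, which is why row and column node
lists may differ.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .codebook import Codebook, load_codebook
from .errors import IntegrityError, ValidationError

ODDS_RATIO = "odds_ratio"
LOG_ODDS = "log_odds"


@dataclass
class EdgeMatrix:
    """Directed weighted network; rows predict columns one wave later."""

    row_nodes: list[str]
    col_nodes: list[str]
    weights: np.ndarray
    scale_tag: str = ODDS_RATIO

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.row_nodes), len(self.col_nodes)):
            raise ValidationError(
                f"weights shape {self.weights.shape} does not match "
                f"{len(self.row_nodes)} rows x {len(self.col_nodes)} cols"
            )
        if len(set(self.row_nodes)) != len(self.row_nodes):
            raise ValidationError("duplicate row nodes")
        if len(set(self.col_nodes)) != len(self.col_nodes):
            raise ValidationError("duplicate column nodes")
        if self.scale_tag not in (ODDS_RATIO, LOG_ODDS):
            raise ValidationError(f"unknown scale_tag {self.scale_tag!r}")
        if self.scale_tag == ODDS_RATIO and not np.all(self.weights > 0):
            raise ValidationError("odds-ratio weights must be strictly positive")
        self._row_index = {c: i for i, c in enumerate(self.row_nodes)}
        self._col_index = {c: j for j, c in enumerate(self.col_nodes)}

    # -- access ---------------------------------------------------------
    def weight(self, source: str, target: str) -> float:
        try:
            return float(self.weights[self._row_index[source], self._col_index[target]])
        except KeyError as exc:
            raise KeyError(f"node {exc.args[0]!r} not in network") from None

    @property
    def is_square(self) -> bool:
        return self.row_nodes == self.col_nodes

    def diagonal_pairs(self) -> list[tuple[int, int]]:
        """(row, col) index pairs of autoregressive cells (same code both axes)."""
        return [
            (i, self._col_index[c])
            for i, c in enumerate(self.row_nodes)
            if c in self._col_index
        ]

    def autoregressive_mask(self) -> np.ndarray:
        mask = np.zeros(self.weights.shape, dtype=bool)
        for i, j in self.diagonal_pairs():
            mask[i, j] = True
        return mask

    def to_log_odds(self) -> "EdgeMatrix":
        if self.scale_tag == LOG_ODDS:
            return self
        return EdgeMatrix(list(self.row_nodes), list(self.col_nodes),
                          np.log(self.weights), LOG_ODDS)

    def to_odds_ratio(self) -> "EdgeMatrix":
        if self.scale_tag == ODDS_RATIO:
            return self
        return EdgeMatrix(list(self.row_nodes), list(self.col_nodes),
                          np.exp(self.weights), ODDS_RATIO)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.row_nodes, columns=self.col_nodes)

    def copy(self) -> "EdgeMatrix":
        return EdgeMatrix(list(self.row_nodes), list(self.col_nodes),
                          self.weights.copy(), self.scale_tag)


def load_table2_fixture(codebook: Codebook | None = None) -> EdgeMatrix:
    """The published T1 -> T2 adjacency matrix, verbatim at 2-decimal precision.

    32 predictor rows (PHYS1...PSYS8, including PSYS7) by 31 outcome columns
    (the PSYS7 column is absent as printed). All weights are odds ratios.

    Raises
    ------
    IntegrityError
        If the shipped file does not pass its structural checks.
    """
    codebook = codebook or load_codebook()
    ref = resources.files("clpnkit.data").joinpath("t1_t2_adjacency.csv")
    with ref.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, index_col=0)
    rows = list(df.index)
    cols = list(df.columns)
    if rows != codebook.codes:
        raise IntegrityError("fixture rows do not match the 32-symptom codebook order")
    expected_cols = [c for c in codebook.codes if c != "PSYS7"]
    if cols != expected_cols:
        raise IntegrityError("fixture columns must be the codebook minus PSYS7")
    w = df.to_numpy(dtype=float)
    if w.shape != (32, 31):
        raise IntegrityError(f"fixture shape {w.shape}, expected (32, 31)")
    if not np.all(np.isfinite(w)) or not np.all(w > 0):
        raise IntegrityError("fixture weights must be finite and strictly positive")
    matrix = EdgeMatrix(rows, cols, w, ODDS_RATIO)
    if len(matrix.diagonal_pairs()) != 31:
        raise IntegrityError("fixture must have 31 autoregressive cells")
    return matrix


_FORMATS = ("edge_list", "graphml")


def _retained_edges(matrix: EdgeMatrix):
    """Edges whose weight differs from the no-association value."""
    null = 1.0 if matrix.scale_tag == ODDS_RATIO else 0.0
    for i, src in enumerate(matrix.row_nodes):
        for j, tgt in enumerate(matrix.col_nodes):
            w = matrix.weights[i, j]
            if w != null:
                yield src, tgt, w


def write_network(matrix: EdgeMatrix, path: str | Path, format: str = "edge_list") -> Path:
    """Write a network to ``edge_list`` (CSV) or ``graphml``.

    Cells at the no-association value (OR = 1) are omitted as absent edges.
    The edge-list format round-trips retained weights bit-exactly.
    """
    path = Path(path)
    if format == "edge_list":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "weight"])
            for src, tgt, w in _retained_edges(matrix):
                writer.writerow([src, tgt, repr(float(w))])
    elif format == "graphml":
        g = nx.DiGraph(scale_tag=matrix.scale_tag)
        g.add_nodes_from(dict.fromkeys(matrix.row_nodes + matrix.col_nodes))
        for src, tgt, w in _retained_edges(matrix):
            g.add_edge(src, tgt, weight=float(w))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {format!r}; choose from {_FORMATS}")
    return path


def read_network(
    path: str | Path,
    format: str = "edge_list",
    row_nodes: list[str] | None = None,
    col_nodes: list[str] | None = None,
    scale_tag: str = ODDS_RATIO,
) -> EdgeMatrix:
    """Read a network written by :func:`write_network`.

    Node lists default to the canonical codebook order; nodes appearing in
    the file but not in the lists raise a ``ValidationError``. Cells without
    a stored edge are filled with the no-association value.
    """
    path = Path(path)
    codes = load_codebook().codes
    row_nodes = list(row_nodes) if row_nodes is not None else codes
    col_nodes = list(col_nodes) if col_nodes is not None else codes
    null = 1.0 if scale_tag == ODDS_RATIO else 0.0
    w = np.full((len(row_nodes), len(col_nodes)), null, dtype=float)
    ri = {c: i for i, c in enumerate(row_nodes)}
    ci = {c: j for j, c in enumerate(col_nodes)}

    def _set(src, tgt, val):
        if src not in ri or tgt not in ci:
            raise ValidationError(f"edge {src}->{tgt} has a node outside the node lists")
        w[ri[src], ci[tgt]] = val

    if format == "edge_list":
        with path.open("r", newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or set(reader.fieldnames) < {"source", "target", "weight"}:
                raise ValidationError("edge list must have source,target,weight columns")
            for rec in reader:
                _set(rec["source"], rec["target"], float(rec["weight"]))
    elif format == "graphml":
        g = nx.read_graphml(path)
        for src, tgt, data in g.edges(data=True):
            _set(src, tgt, float(data["weight"]))
    else:
        raise ValueError(f"unknown format {format!r}; choose from {_FORMATS}")
    return EdgeMatrix(row_nodes, col_nodes, w, scale_tag)
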