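"""Expected-influence centralities for directed symptom networks.

Expected influence (EI) aggregates signed edge weights, so inhibitory
(OR < 1) edges count against a node rather than toward it. For a directed
cross-lagged network the roles split: out-EI sums a node's outgoing
cross-lagged edges (how strongly a symptom at T1 predicts other symptoms at
T2), in-EI its incoming edges (how strongly it is predicted), and bridge-EI
restricts the sum to edges crossing symptom-domain communities (physical /
cognitive / psychological), in both directions — the quantity used to flag
bridge symptoms. Autoregressive (diagonal) edges are always excluded.

Edge weights enter on a signed transform of the OR: ln(OR) by default
(identical to the underlying regression coefficients) or OR - 1. Both are
monotone around 1 and give identical rankings for the edge magnitudes seen
in practice.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import AlignmentError
from .network import ODDS_RATIO, EdgeMatrix

LOG_SCALE = "log_odds"
OR_MINUS_ONE = "or_minus_one"


def _transformed(matrix: EdgeMatrix, scale: str) -> np.ndarray:
    w = matrix.weights if matrix.scale_tag == ODDS_RATIO else np.exp(matrix.weights)
    if scale == LOG_SCALE:
        return np.log(w)
    if scale == OR_MINUS_ONE:
        return w - 1.0
    raise ValueError(f"unknown scale {scale!r}")


def out_ei(matrix: EdgeMatrix, scale: str = LOG_SCALE) -> pd.Series:
    """Per-row-node sum of transformed outgoing cross-lagged weights."""
    t = _transformed(matrix, scale)
    t = np.where(matrix.autoregressive_mask(), 0.0, t)
    return pd.Series(t.sum(axis=1), index=matrix.row_nodes, name="out_ei")


def in_ei(matrix: EdgeMatrix, scale: str = LOG_SCALE) -> pd.Series:
    """Per-column-node sum of transformed incoming cross-lagged weights."""
    t = _transformed(matrix, scale)
    t = np.where(matrix.autoregressive_mask(), 0.0, t)
    return pd.Series(t.sum(axis=0), index=matrix.col_nodes, name="in_ei")


def bridge_ei(matrix: EdgeMatrix, partition: dict[str, str],
              scale: str = LOG_SCALE) -> pd.Series:
    """Per-node sum of transformed cross-community edges, outgoing + incoming.

    Nodes present only among the rows (no outcome column) accumulate only
    the outgoing half. Every node must have a community.
    """
    nodes = list(dict.fromkeys(matrix.row_nodes + matrix.col_nodes))
    missing = [c for c in nodes if c not in partition]
    if missing:
        raise AlignmentError(f"nodes without a community: {missing}")
    t = _transformed(matrix, scale)
    auto = matrix.autoregressive_mask()
    cross = np.array([[partition[r] != partition[c] for c in matrix.col_nodes]
                      for r in matrix.row_nodes])
    contrib = np.where(cross & ~auto, t, 0.0)
    out_part = pd.Series(contrib.sum(axis=1), index=matrix.row_nodes)
    in_part = pd.Series(contrib.sum(axis=0), index=matrix.col_nodes)
    total = out_part.reindex(nodes, fill_value=0.0) + in_part.reindex(nodes, fill_value=0.0)
    total.name = "bridge_ei"
    return total


def centrality_table(matrix: EdgeMatrix, partition: dict[str, str],
                     scale: str = LOG_SCALE) -> pd.DataFrame:
    """Raw out-EI, in-EI and bridge-EI per node (codebook/row order).

    Nodes without an outcome column (e.g. a predictor-only node in a
    printed, asymmetric matrix) get NaN in-EI rather than 0.
    """
    nodes = list(dict.fromkeys(matrix.row_nodes + matrix.col_nodes))
    table = pd.DataFrame(index=pd.Index(nodes, name="node"))
    table["out_ei"] = out_ei(matrix, scale).reindex(nodes)
    table["in_ei"] = in_ei(matrix, scale).reindex(nodes)   # NaN where absent
    table["bridge_ei"] = bridge_ei(matrix, partition, scale).reindex(nodes)
    return table


def zscore(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score each centrality column over nodes (population scaling).

    Constant columns become all-zero with a warning. NaN entries (nodes for
    which a metric is undefined) stay NaN and are excluded from the moments.
    """
    if len(table) < 2:
        raise ValueError("z-scoring needs >= 2 nodes")
    out = table.copy()
    for col in table.columns:
        v = table[col].to_numpy(dtype=float)
        obs = v[~np.isnan(v)]
        sd = obs.std()
        if sd == 0:
            warnings.warn(f"centrality column {col!r} is constant; z-scores set to 0",
                          stacklevel=2)
            out[col] = np.where(np.isnan(v), np.nan, 0.0)
        else:
            out[col] = (v - obs.mean()) / sd
    return out


def filter_edges(matrix: EdgeMatrix, min_or: float,
                 keep_negative_mirror: bool = True) -> EdgeMatrix:
    """Display filter: keep only strong cross-lagged edges.

    Off-diagonal weights with OR below ``min_or`` are set absent (OR = 1);
    when ``keep_negative_mirror``, negative edges at least as strong
    (OR <= 1/min_or) are preserved. Autoregressive cells are dropped.
    """
    if min_or <= 0:
        raise ValueError("min_or must be positive")
    m = matrix.to_odds_ratio().copy()
    keep = m.weights >= min_or
    if keep_negative_mirror:
        keep |= m.weights <= 1.0 / min_or
    w = np.where(keep, m.weights, 1.0)
    w[m.autoregressive_mask()] = 1.0
    return EdgeMatrix(list(m.row_nodes), list(m.col_nodes), w, ODDS_RATIO)


def strongest_edges(matrix: EdgeMatrix, k: int) -> list[tuple[str, str, float]]:
    """Top-k cross-lagged edges by |ln OR|, descending.

    Ties are broken by (row, column) position, i.e. codebook order of the
    (source, target) pair.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    m = matrix.to_odds_ratio()
    strength = np.abs(np.log(m.weights))
    strength[m.autoregressive_mask()] = -np.inf
    entries = [(-strength[i, j], i, j)
               for i in range(len(m.row_nodes)) for j in range(len(m.col_nodes))
               if np.isfinite(strength[i, j]) and strength[i, j] > 0]
    entries.sort()
    return [(m.row_nodes[i], m.col_nodes[j], float(m.weights[i, j]))
            for _, i, j in entries[:k]]
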