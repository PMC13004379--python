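"""Bootstrap accuracy and stability for estimated cross-lagged networks.

Three pieces of machinery, all pure functions of (panel, config, seed):

* nonparametric bootstrap of edge weights — resample completers with
  replacement, re-estimate the network, and report percentile confidence
  intervals per edge;
* case-drop bootstrap correlation-stability (CS) coefficients — for a grid
  of drop proportions, re-estimate on retained subsamples and correlate
  each centrality metric with its full-sample value; the CS coefficient is
  the largest drop proportion at which at least 95% of correlations stay
  >= 0.7 (the conventional thresholds);
* centrality difference tests — for each node pair, a percentile bootstrap
  interval of the centrality difference; the pair differs significantly
  when the interval excludes zero (no multiplicity correction, matching
  common practice).

By default every re-estimation re-runs the full cross-validated lambda
selection — the honest but slow variant. ``reselect_lambda=False`` fixes
each node's lambda at its full-sample selection and refits only the
penalized solution per resample; this is much faster and is labelled in the
output it produces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import centrality as _centrality
from .centrality import LOG_SCALE
from .errors import AlignmentError, ClpnError, DegenerateFitError
from .estimation import FitConfig, estimate_network
from .network import ODDS_RATIO, EdgeMatrix
from .panel import TwoWavePanel

_METRICS = ("out_ei", "in_ei", "bridge_ei")


def _resample(panel: TwoWavePanel, rng: np.random.Generator,
              n_keep: int | None = None, with_replacement: bool = True) -> TwoWavePanel:
    df = panel.data
    n = len(df)
    if with_replacement:
        idx = rng.integers(0, n, n)
    else:
        idx = rng.choice(n, n_keep, replace=False)
    sub = df.iloc[idx].reset_index(drop=True)
    sub = sub.assign(participant_id=[f"R{i}" for i in range(len(sub))])
    return TwoWavePanel(sub, panel.codebook, validate=False)


def _estimate(panel: TwoWavePanel, config: FitConfig,
              fixed_lambdas: dict[str, float] | None) -> EdgeMatrix:
    if fixed_lambdas is None:
        return estimate_network(panel, config)
    codes = panel.codebook.codes
    weights = np.ones((len(codes), len(codes)))
    from .estimation import fit_node_at_lambda
    completers = panel.completers()
    t1 = completers.scores("T1")
    t2 = completers.scores("T2")
    cov = completers.covariates(config.covariates) if config.covariates else None
    for j, code in enumerate(codes):
        y = t2[code].to_numpy(dtype=float)
        if config.family == "binomial":
            y = (y > 0).astype(float)
        fit = fit_node_at_lambda(y, t1, cov, config, fixed_lambdas[code],
                                 outcome_name=code)
        weights[:, j] = np.exp(fit.symptom_coefficients.to_numpy(dtype=float))
    return EdgeMatrix(list(codes), list(codes), weights, ODDS_RATIO)


def _full_sample_lambdas(panel: TwoWavePanel, config: FitConfig) -> dict[str, float]:
    _, fits = estimate_network(panel, config, return_fits=True)
    return {code: fit.selected_lambda for code, fit in fits.items()}


@dataclass
class BootstrapEdgeSummary:
    """Per-edge bootstrap distribution summary."""

    edges: pd.DataFrame          # source, target, estimate, boot_mean, ci_lower, ci_upper
    n_boot: int
    n_failed: int
    seed: int | None
    ci_level: float
    reselect_lambda: bool

    def ci(self, source: str, target: str) -> tuple[float, float]:
        row = self.edges[(self.edges["source"] == source)
                         & (self.edges["target"] == target)]
        if row.empty:
            raise KeyError(f"edge {source}->{target} not in summary")
        return float(row["ci_lower"].iloc[0]), float(row["ci_upper"].iloc[0])


def bootstrap_edges(panel: TwoWavePanel, config: FitConfig | None = None,
                    n_boot: int = 1000, seed: int | None = None,
                    ci_level: float = 0.95,
                    reselect_lambda: bool = True) -> BootstrapEdgeSummary:
    """Nonparametric bootstrap CIs for every edge weight (OR scale).

    Completers are resampled with replacement ``n_boot`` times and the
    network re-estimated per resample. Resamples with a degenerate fit
    (e.g. a constant outcome column) are excluded and counted in
    ``n_failed``. Reproducible given ``seed``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    config = config or FitConfig()
    completers = panel.completers()
    point = estimate_network(completers, config)
    fixed = None if reselect_lambda else _full_sample_lambdas(completers, config)
    rng = np.random.default_rng(seed)
    draws = []
    n_failed = 0
    for _ in range(n_boot):
        sample = _resample(completers, rng)
        try:
            est = _estimate(sample, config, fixed)
        except (DegenerateFitError, ClpnError):
            n_failed += 1
            continue
        draws.append(est.weights)
    if not draws:
        raise ClpnError("all bootstrap resamples failed")
    stack = np.stack(draws)
    alpha = 1.0 - ci_level
    lo = np.quantile(stack, alpha / 2, axis=0)
    hi = np.quantile(stack, 1 - alpha / 2, axis=0)
    mean = stack.mean(axis=0)
    codes = point.row_nodes
    records = []
    for i, src in enumerate(codes):
        for j, tgt in enumerate(point.col_nodes):
            records.append({"source": src, "target": tgt,
                            "estimate": point.weights[i, j],
                            "boot_mean": mean[i, j],
                            "ci_lower": lo[i, j], "ci_upper": hi[i, j]})
    return BootstrapEdgeSummary(pd.DataFrame(records), len(draws), n_failed,
                                seed, ci_level, reselect_lambda)


def _metric_values(matrix: EdgeMatrix, metric: str,
                   partition: dict[str, str] | None, scale: str) -> pd.Series:
    if metric == "out_ei":
        return _centrality.out_ei(matrix, scale)
    if metric == "in_ei":
        return _centrality.in_ei(matrix, scale)
    if metric == "bridge_ei":
        if partition is None:
            raise ValueError("bridge_ei requires a community partition")
        return _centrality.bridge_ei(matrix, partition, scale)
    raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")


@dataclass
class CSResult:
    """Case-drop correlation-stability summary for one centrality metric."""

    metric: str
    drop_grid: np.ndarray
    correlations: dict[float, np.ndarray]   # per proportion, one r per subsample
    proportion_ok: dict[float, float]       # share of correlations >= threshold
    cs_coefficient: float
    n_boot: int
    seed: int | None
    correlation_threshold: float = 0.7
    confidence: float = 0.95


DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.76, 0.05), 2))


def case_drop_cs(panel: TwoWavePanel, config: FitConfig | None = None,
                 metric: str = "bridge_ei",
                 drop_grid: tuple[float, ...] = DEFAULT_DROP_GRID,
                 n_boot: int = 100, seed: int | None = None,
                 partition: dict[str, str] | None = None,
                 scale: str = LOG_SCALE,
                 correlation_threshold: float = 0.7,
                 confidence: float = 0.95,
                 reselect_lambda: bool = True) -> CSResult:
    """Case-drop bootstrap CS coefficient for a centrality metric.

    For each drop proportion p, draws ``n_boot`` subsamples retaining
    (1-p)*n completers, re-estimates the network, and correlates the metric
    with its full-sample value. CS = the largest p at which at least
    ``confidence`` of the correlations reach ``correlation_threshold``
    (0 when no proportion qualifies).
    """
    grid = np.asarray(sorted(drop_grid), dtype=float)
    if np.any((grid <= 0) | (grid > 0.95)):
        raise ValueError("drop proportions must lie in (0, 0.95]")
    config = config or FitConfig()
    partition = partition or panel.codebook.partition()
    completers = panel.completers()
    n = len(completers)
    full = _metric_values(estimate_network(completers, config), metric,
                          partition, scale)
    fixed = None if reselect_lambda else _full_sample_lambdas(completers, config)
    rng = np.random.default_rng(seed)
    correlations: dict[float, np.ndarray] = {}
    proportion_ok: dict[float, float] = {}
    for p in grid:
        n_keep = int(round((1 - p) * n))
        if n_keep < 2 * config.n_folds:
            warnings.warn(f"drop proportion {p}: retained n={n_keep} too small; skipped",
                          stacklevel=2)
            continue
        rs = np.empty(n_boot)
        for b in range(n_boot):
            sub = _resample(completers, rng, n_keep=n_keep, with_replacement=False)
            try:
                est = _estimate(sub, config, fixed)
            except (DegenerateFitError, ClpnError):
                rs[b] = np.nan
                continue
            vals = _metric_values(est, metric, partition, scale)
            a = vals.reindex(full.index).to_numpy(dtype=float)
            b_ = full.to_numpy(dtype=float)
            if np.std(a) == 0 or np.std(b_) == 0:
                rs[b] = 0.0
            else:
                rs[b] = np.corrcoef(a, b_)[0, 1]
        rs = rs[~np.isnan(rs)]
        correlations[float(p)] = rs
        proportion_ok[float(p)] = (float(np.mean(rs >= correlation_threshold))
                                   if rs.size else 0.0)
    qualifying = [p for p, ok in proportion_ok.items() if ok >= confidence]
    cs = max(qualifying) if qualifying else 0.0
    return CSResult(metric, grid, correlations, proportion_ok, float(cs),
                    n_boot, seed, correlation_threshold, confidence)


def bootstrap_centralities(panel: TwoWavePanel, config: FitConfig | None = None,
                           metric: str = "out_ei", n_boot: int = 100,
                           seed: int | None = None,
                           partition: dict[str, str] | None = None,
                           scale: str = LOG_SCALE,
                           reselect_lambda: bool = True) -> pd.DataFrame:
    """Bootstrap draws (rows) of a centrality metric per node (columns)."""
    config = config or FitConfig()
    partition = partition or panel.codebook.partition()
    completers = panel.completers()
    fixed = None if reselect_lambda else _full_sample_lambdas(completers, config)
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_boot):
        sample = _resample(completers, rng)
        try:
            est = _estimate(sample, config, fixed)
        except (DegenerateFitError, ClpnError):
            continue
        rows.append(_metric_values(est, metric, partition, scale))
    return pd.DataFrame(rows).reset_index(drop=True)


def centrality_difference_test(draws: pd.DataFrame,
                               alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise significant-difference matrix from bootstrap centrality draws.

    ``draws`` has one row per bootstrap draw and one column per node. A
    pair differs significantly when the (1 - alpha) percentile interval of
    the bootstrap distribution of their difference excludes zero. The
    result is a symmetric boolean DataFrame with a False diagonal.
    """
    if len(draws) < 2:
        raise ValueError("need >= 2 bootstrap draws")
    if draws.isna().any().any():
        raise AlignmentError("draws contain missing values; node sets must match "
                             "across all draws")
    nodes = list(draws.columns)
    values = draws.to_numpy(dtype=float)
    sig = pd.DataFrame(False, index=nodes, columns=nodes)
    lo_q, hi_q = alpha / 2, 1 - alpha / 2
    for i, a in enumerate(nodes):
        diffs = values[:, i][:, None] - values[:, i + 1:]
        if diffs.shape[1] == 0:
            continue
        lo = np.quantile(diffs, lo_q, axis=0)
        hi = np.quantile(diffs, hi_q, axis=0)
        flag = (lo > 0) | (hi < 0)
        for off, b in enumerate(nodes[i + 1:]):
            sig.loc[a, b] = sig.loc[b, a] = bool(flag[off])
    return sig
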