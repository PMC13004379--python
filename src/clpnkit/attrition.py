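"""Completer-vs-dropout group comparisons for two-wave panels.

Attrition analysis asks whether participants lost to follow-up differ at
baseline from those retained. For categorical baseline variables the module
offers the Pearson chi-square, the likelihood-ratio (G-squared) chi-square,
Fisher's exact test (2x2) and a seeded Monte Carlo analogue for larger
tables; for continuous variables a one-way ANOVA F test. Each result
records which statistic was computed — the tests are never switched
silently, so any published cell can be reproduced by naming its method.
P-values are reported unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .errors import DegenerateFitError, SchemaError
from .panel import TwoWavePanel

PEARSON_CHI2 = "pearson_chi2"
LR_CHI2 = "lr_chi2"
FISHER_EXACT = "fisher_exact"
FISHER_MC = "fisher_mc"
ANOVA_F = "anova_f"


@dataclass(frozen=True)
class ContingencyTable:
    """Categories x groups count table (groups: missing vs completion)."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("contingency table needs >= 2 rows and columns")
        if np.any(counts < 0) or np.any(counts != np.round(counts)):
            raise ValueError("counts must be non-negative integers")

    def check_margins(self) -> None:
        if np.any(self.counts.sum(axis=0) == 0) or np.any(self.counts.sum(axis=1) == 0):
            raise DegenerateFitError("contingency table has a zero margin")


def table_from_groups(missing: list[int], completion: list[int],
                      row_labels: tuple[str, ...] | None = None) -> ContingencyTable:
    """Build a categories x (missing, completion) table from two count lists."""
    if len(missing) != len(completion):
        raise ValueError("group count lists must have equal length")
    rows = row_labels or tuple(f"cat{i}" for i in range(len(missing)))
    counts = np.column_stack([missing, completion])
    return ContingencyTable(rows, ("missing", "completion"), counts)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str
    detail: dict = field(default_factory=dict)


def pearson_chi2(table: ContingencyTable) -> TestResult:
    """Pearson chi-square test of independence (no continuity correction)."""
    table.check_margins()
    res = stats.chi2_contingency(table.counts, correction=False)
    return TestResult(float(res.statistic), int(res.dof), float(res.pvalue), PEARSON_CHI2)


def lr_chi2(table: ContingencyTable) -> TestResult:
    """Likelihood-ratio (G-squared) chi-square test of independence."""
    table.check_margins()
    res = stats.chi2_contingency(table.counts, correction=False,
                                 lambda_="log-likelihood")
    return TestResult(float(res.statistic), int(res.dof), float(res.pvalue), LR_CHI2)


def fisher_exact(table: ContingencyTable) -> TestResult:
    """Fisher's exact test (two-sided) for 2x2 tables."""
    if table.counts.shape != (2, 2):
        raise ValueError("fisher_exact handles 2x2 tables only; use fisher_mc "
                         "for larger tables")
    table.check_margins()
    res = stats.fisher_exact(table.counts, alternative="two-sided")
    return TestResult(float(res.statistic), 1, float(res.pvalue), FISHER_EXACT,
                      detail={"statistic_is": "odds_ratio"})


def _log_table_prob(counts: np.ndarray) -> float:
    """Log multivariate hypergeometric probability of a table given its margins."""
    r = counts.sum(axis=1)
    c = counts.sum(axis=0)
    n = counts.sum()
    return float(gammaln(r + 1).sum() + gammaln(c + 1).sum()
                 - gammaln(n + 1) - gammaln(counts + 1).sum())


def fisher_mc(table: ContingencyTable, reps: int = 10_000,
              seed: int | None = None) -> TestResult:
    """Monte Carlo Fisher test for r x c tables.

    Samples ``reps`` tables with the observed margins fixed (Patefield
    sampling) and estimates the two-sided p-value as the probability of a
    table no more likely than the observed one, with the +1 correction that
    keeps the estimate positive and unbiased under the null.
    """
    if reps < 1000:
        raise ValueError("fisher_mc requires reps >= 1000")
    table.check_margins()
    rng = np.random.default_rng(seed)
    obs_logp = _log_table_prob(table.counts)
    dist = stats.random_table(table.counts.sum(axis=1).astype(int),
                              table.counts.sum(axis=0).astype(int))
    samples = dist.rvs(reps, random_state=rng)
    logps = np.array([_log_table_prob(s) for s in samples])
    # tolerance absorbs round-off when comparing equal-probability tables
    hits = int(np.sum(logps <= obs_logp + 1e-9))
    p = (hits + 1) / (reps + 1)
    return TestResult(float("nan"), int((table.counts.shape[0] - 1)
                                        * (table.counts.shape[1] - 1)),
                      float(p), FISHER_MC, detail={"reps": reps, "seed": seed})


def anova_f(*groups) -> TestResult:
    """One-way ANOVA F test across two or more groups of values."""
    if len(groups) < 2:
        raise ValueError("anova_f needs >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise DegenerateFitError("each group needs >= 2 values")
    res = stats.f_oneway(*arrays)
    df1 = len(arrays) - 1
    df2 = sum(len(g) for g in arrays) - len(arrays)
    return TestResult(float(res.statistic), df1, float(res.pvalue), ANOVA_F,
                      detail={"df_within": df2})


def anova_f_from_summary(ns, means, sds) -> TestResult:
    """One-way F reconstructed from per-group (n, mean, sd) summaries."""
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    grand = float(np.sum(ns * means) / ns.sum())
    df1 = len(ns) - 1
    df2 = int(ns.sum()) - len(ns)
    msb = float(np.sum(ns * (means - grand) ** 2) / df1)
    msw = float(np.sum((ns - 1) * sds ** 2) / df2)
    f = msb / msw
    p = float(stats.f.sf(f, df1, df2))
    return TestResult(f, df1, p, ANOVA_F, detail={"df_within": df2,
                                                  "from_summaries": True})


def attrition_report(panel: TwoWavePanel, variables: list[str],
                     methods: dict[str, str] | None = None,
                     mc_reps: int = 10_000, seed: int | None = None) -> pd.DataFrame:
    """Compare completers and dropouts on baseline variables.

    Categorical variables get a chi-square test (Pearson by default;
    override per variable via ``methods`` with one of ``pearson_chi2``,
    ``lr_chi2``, ``fisher_exact``, ``fisher_mc``). ``age`` — or any variable
    mapped to ``anova_f`` — is compared with a one-way F test.
    """
    methods = methods or {}
    completer = panel.completer_mask
    rows = []
    for var in variables:
        if var not in panel.data.columns:
            raise SchemaError(f"variable {var!r} not in panel")
        method = methods.get(var, ANOVA_F if var == "age" else PEARSON_CHI2)
        values = panel.data[var]
        if method == ANOVA_F:
            result = anova_f(values[~completer].to_numpy(dtype=float),
                             values[completer].to_numpy(dtype=float))
        else:
            crosstab = pd.crosstab(values, completer)
            # ensure both groups present and ordered (missing, completion)
            for flag in (False, True):
                if flag not in crosstab.columns:
                    raise DegenerateFitError(f"variable {var!r}: a group is empty")
            counts = np.column_stack([crosstab[False].to_numpy(),
                                      crosstab[True].to_numpy()])
            table = ContingencyTable(tuple(str(i) for i in crosstab.index),
                                     ("missing", "completion"), counts)
            if method == PEARSON_CHI2:
                result = pearson_chi2(table)
            elif method == LR_CHI2:
                result = lr_chi2(table)
            elif method == FISHER_EXACT:
                result = fisher_exact(table)
            elif method == FISHER_MC:
                result = fisher_mc(table, reps=mc_reps, seed=seed)
            else:
                raise ValueError(f"unknown method {method!r} for {var!r}")
        rows.append({"variable": var, "method": result.method,
                     "statistic": result.statistic, "df": result.df,
                     "p_value": result.p_value})
    return pd.DataFrame(rows)
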