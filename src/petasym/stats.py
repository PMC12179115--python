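"""Inferential battery for the hemispheric-asymmetry analysis.

Paired Wilcoxon signed-rank and Mann-Whitney U tests carry in-package exact
null distributions (dynamic programming over rank assignments, identical to
full enumeration) for small tie-free samples, falling back to tie- and
continuity-corrected normal approximations otherwise.  Holm-Sidak step-down
adjustment is implemented in-package.  Shapiro-Wilk and Pearson delegate to
scipy; the random-intercept linear mixed model is backed by statsmodels
MixedLM (REML) with Wald-normal inference, recorded in the result metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "LMEResult",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "shapiro_wilk",
    "holm_sidak_adjust",
    "pearson_correlation",
    "fit_lme_random_intercept",
    "EXACT_WILCOXON_MAX_N",
    "EXACT_MWU_MAX_MIN_N",
]

#: Exact Wilcoxon null distribution used up to this n (tie-free differences).
EXACT_WILCOXON_MAX_N = 25
#: Exact Mann-Whitney used when min(n1, n2) <= this (tie-free pooled sample).
EXACT_MWU_MAX_MIN_N = 8


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    n: int
    n2: int | None = None
    exact: bool = False
    degenerate: bool = False
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p_value - 1e-12:
            raise ValueError("adjusted p-value cannot be below the raw p-value")

    def adjusted(self, p_adj: float) -> "TestResult":
        from dataclasses import replace

        return replace(self, p_adjusted=float(min(p_adj, 1.0)))


def _check_two_sided(alternative: str) -> None:
    if alternative != "two-sided":
        raise NotImplementedError("only two-sided alternatives are supported")


def _symmetric_tail_p(counts: np.ndarray, stat: int) -> float:
    """Two-sided p from an integer-valued null pmf symmetric on [0, M]."""
    m = counts.size - 1
    lo = min(stat, m - stat)
    hi = m - lo
    total = counts.sum()
    if hi <= lo:
        return 1.0
    p = (counts[: lo + 1].sum() + counts[hi:].sum()) / total
    return float(min(p, 1.0))


def _signed_rank_counts(n: int) -> np.ndarray:
    """Exact null counts of W+ over all 2^n sign assignments of ranks 1..n."""
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1, dtype=float)
    counts[0] = 1.0
    for rank in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[rank:] = counts[:-rank] if rank > 0 else counts
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    alternative: str = "two-sided",
) -> TestResult:
    """Paired Wilcoxon signed-rank test on d = x - y (zero differences dropped).

    Exact two-sided p by the full sign-assignment null distribution for
    n <= 25 without ties in |d|; tie- and continuity-corrected normal
    approximation otherwise.  All differences zero yields p = 1 with a
    degenerate flag rather than an error.
    """
    _check_two_sided(alternative)
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    if y is not None and len(x) != len(np.asarray(y)):
        raise ValueError("paired samples must have equal length")
    d = d[np.isfinite(d)]
    nonzero = d[d != 0.0]
    n = nonzero.size
    if n == 0:
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0, 0, degenerate=True)
    if n < 3:
        raise ValueError("need at least 3 non-zero paired differences")
    ranks = sps.rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    has_ties = np.unique(np.abs(nonzero)).size < n

    if n <= EXACT_WILCOXON_MAX_N and not has_ties:
        counts = _signed_rank_counts(n)
        p = _symmetric_tail_p(counts, int(round(w_plus)))
        return TestResult("wilcoxon_signed_rank", w_plus, p, n, exact=True)

    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(np.abs(nonzero), return_counts=True)
    var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    num = w_plus - mu
    num -= np.sign(num) * 0.5  # continuity correction toward the mean
    if abs(w_plus - mu) < 0.5:
        num = 0.0
    z = num / np.sqrt(var) if var > 0 else 0.0
    p = float(min(2.0 * sps.norm.sf(abs(z)), 1.0))
    return TestResult("wilcoxon_signed_rank", w_plus, p, n, exact=False)


def _rank_sum_counts(n1: int, n_total: int) -> np.ndarray:
    """Counts of rank sums over all C(n_total, n1) subsets of ranks 1..n_total."""
    max_sum = sum(range(n_total - n1 + 1, n_total + 1))
    table = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    table[0, 0] = 1.0
    for v in range(1, n_total + 1):
        for k in range(min(n1, v), 0, -1):
            table[k, v:] += table[k - 1, : max_sum + 1 - v]
    return table[n1]


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> TestResult:
    """Mann-Whitney U test of two independent samples.

    Exact null distribution (all rank labelings) when min(n1, n2) <= 8 and the
    pooled sample is tie-free; tie-corrected normal approximation otherwise.
    """
    _check_two_sided(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    has_ties = np.unique(pooled).size < pooled.size

    if min(n1, n2) <= EXACT_MWU_MAX_MIN_N and not has_ties:
        counts = _rank_sum_counts(n1, n1 + n2)
        # shift rank-sum pmf to the U scale: U = R1 - n1(n1+1)/2
        offset = n1 * (n1 + 1) // 2
        u_counts = counts[offset:]
        p = _symmetric_tail_p(u_counts, int(round(u1)))
        return TestResult("mann_whitney_u", u1, p, n1, n2=n2, exact=True)

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    num = u1 - mu
    num -= np.sign(num) * 0.5
    if abs(u1 - mu) < 0.5:
        num = 0.0
    z = num / np.sqrt(var) if var > 0 else 0.0
    p = float(min(2.0 * sps.norm.sf(abs(z)), 1.0))
    return TestResult("mann_whitney_u", u1, p, n1, n2=n2, exact=False)


def shapiro_wilk(x: Sequence[float]) -> TestResult:
    """Shapiro-Wilk normality test (scipy implementation)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    res = sps.shapiro(x)
    return TestResult("shapiro_wilk", float(res.statistic), float(res.pvalue), x.size)


def holm_sidak_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, returned in the input order.

    Sorted ascending, the i-th (1-based) adjusted value is
    ``1 - (1 - p_(i))^(m - i + 1)``, made monotone non-decreasing over the
    sorted order and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson r with the two-sided p from the t transform on n - 2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation is undefined for constant input")
    res = sps.pearsonr(x, y)
    return TestResult("pearson", float(res.statistic), float(res.pvalue), x.size)


# ----------------------------------------------------------------------------
# random-intercept linear mixed model
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class LMEResult:
    """Fixed effects (Wald-normal SEs, CIs, p) and variance components."""

    table: pd.DataFrame
    var_subject: float
    var_residual: float
    n_subjects: int
    n_rows: int
    df_method: str = "wald_z"
    converged: bool = True

    def effect(self, term: str) -> pd.Series:
        rows = self.table[self.table.term == term]
        if rows.empty:
            raise KeyError(f"no fixed effect named {term!r}")
        return rows.iloc[0]


_COVARIATE_COLUMNS = {
    "age": ("age", None),
    "sex": ("sex_male", "male"),
    "handedness": ("handedness_right", "right"),
    "centre": ("centre_turku", "Turku"),
}


def _build_design(
    data: pd.DataFrame,
    covariates: Sequence[str],
    interaction: bool,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    df = data.copy()
    required = {"subject_id", "hemisphere", "DVR"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"LME table lacks columns {sorted(missing)}")
    if "handedness" in covariates:
        df = df[df["handedness"] != "unknown"].copy()
    counts = df.groupby("subject_id").size()
    if not (counts == 2).all():
        bad = counts[counts != 2].index[0]
        raise ValueError(f"subject {bad!r} does not contribute exactly two rows")
    cols: dict[str, np.ndarray] = {
        "Intercept": np.ones(len(df)),
        "hemisphere_right": (df["hemisphere"] == "right").to_numpy(float),
    }
    for cov in covariates:
        if cov not in _COVARIATE_COLUMNS:
            raise ValueError(f"unknown covariate {cov!r}")
        name, level = _COVARIATE_COLUMNS[cov]
        if cov == "age":
            cols[name] = df["age"].to_numpy(float)
        else:
            cols[name] = (df[cov] == level).to_numpy(float)
    if interaction:
        if "centre" not in covariates:
            raise ValueError("centre-by-hemisphere interaction requires the centre term")
        cols["centre_turku:hemisphere_right"] = (
            cols["centre_turku"] * cols["hemisphere_right"]
        )
    exog = np.column_stack(list(cols.values()))
    names = list(cols.keys())
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        for j in range(exog.shape[1] - 1, -1, -1):
            others = np.delete(exog, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                raise ValueError(
                    f"singular fixed-effects design: term {names[j]!r} is collinear"
                )
        raise ValueError("singular fixed-effects design")
    return df, exog, names


def fit_lme_random_intercept(
    data: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex", "handedness", "centre"),
    interaction: bool = True,
    min_subjects: int = 10,
) -> LMEResult:
    """REML random-intercept model of DVR on hemisphere and covariates.

    ``data`` is long format with one row per subject x hemisphere and columns
    subject_id, hemisphere (left/right), DVR, plus any requested covariates
    (age, sex, handedness, centre).  Subjects with unknown handedness are
    excluded before fitting whenever handedness is a covariate.  Reference
    levels: left hemisphere, female, left-handed, Manchester.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    interaction = interaction and "centre" in covariates
    df, exog, names = _build_design(data, covariates, interaction)
    n_subjects = df["subject_id"].nunique()
    if n_subjects < min_subjects:
        raise ValueError(f"need at least {min_subjects} subjects, got {n_subjects}")
    endog = df["DVR"].to_numpy(float)
    model = sm.MixedLM(endog, exog, groups=df["subject_id"].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        result = model.fit(reml=True, method=["lbfgs", "bfgs"])
    k = len(names)
    est = np.asarray(result.fe_params, dtype=float)[:k]
    se = np.asarray(result.bse, dtype=float)[:k]
    z = np.divide(est, se, out=np.zeros_like(est), where=se > 0)
    p = 2.0 * sps.norm.sf(np.abs(z))
    ci_low = est - 1.959963984540054 * se
    ci_high = est + 1.959963984540054 * se
    table = pd.DataFrame(
        {
            "term": names,
            "estimate": est,
            "se": se,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "p_value": p,
        }
    )
    return LMEResult(
        table=table,
        var_subject=float(np.asarray(result.cov_re)[0, 0]),
        var_residual=float(result.scale),
        n_subjects=int(n_subjects),
        n_rows=int(len(df)),
        converged=bool(result.converged),
    )
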