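"""Descriptive statistics and profile-difference tests.

Categorical characteristics are compared across profiles with a Pearson
chi-square (Yates continuity correction on 2x2 tables), falling back to
Fisher's exact test when expected counts are too small; ordinal and
continuous scores use the Mann-Whitney U test with the tie-corrected
normal approximation. Scale reliability (Cronbach's alpha) and pairwise
Spearman correlations of the six scale totals are provided as utilities.

The sparse-cell screen implements the rule that defines the candidate
set for stability selection: a categorical variable with fewer than 10
observations in any profile-by-level cell is kept for description only
and excluded from multivariate modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import SCALE_RANGES
from .lpa import HIGH_LABEL, LOW_LABEL


class UnivariateError(ValueError):
    pass


@dataclass
class TestResult:
    method: str  # chi_square_yates | chi_square | fisher_exact | mann_whitney
    statistic: Optional[float]
    p_value: float
    df: Optional[int] = None
    notes: dict = field(default_factory=dict)


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise UnivariateError("contingency table must be at least 2x2")
    if (t < 0).any() or t.sum() <= 0:
        raise UnivariateError("contingency table needs non-negative counts with a positive total")
    return t


def chi_square(table) -> TestResult:
    """Pearson chi-square; Yates continuity correction on 2x2 tables."""
    t = _as_table(table)
    expected = stats.contingency.expected_freq(t)
    if (expected == 0).any():
        raise UnivariateError("zero expected count; use fisher_exact instead")
    yates = t.shape == (2, 2)
    stat, p, dof, _ = stats.chi2_contingency(t, correction=yates)
    return TestResult(
        method="chi_square_yates" if yates else "chi_square",
        statistic=float(stat),
        p_value=float(p),
        df=int(dof),
    )


_ENUMERATION_CAP = 200
_ENUMERATION_WORK_CAP = 200_000
_MC_DRAWS = 100_000


def fisher_exact(table, seed: int | None = None) -> TestResult:
    """Fisher's exact test for r x c tables.

    2x2 tables use the exact hypergeometric two-sided p. Larger tables
    use exact enumeration over all tables with the observed margins when
    the grand total is at most 200 and the enumeration is tractable;
    beyond that a Monte-Carlo p with 1e5 permutation draws and the
    (1+#)/(B+1) estimator is reported and flagged in the notes.
    """
    t = _as_table(table)
    notes: dict = {}
    if t.shape == (2, 2):
        _, p = stats.fisher_exact(t.astype(int))
    elif t.sum() <= _ENUMERATION_CAP and _enumeration_work(t.astype(int)) <= _ENUMERATION_WORK_CAP:
        p = _fisher_enumerate(t.astype(int))
    else:
        p = _fisher_montecarlo(t.astype(int), seed=seed)
        notes["monte_carlo"] = _MC_DRAWS
    return TestResult(method="fisher_exact", statistic=None, p_value=float(p), notes=notes)


def _enumeration_work(t: np.ndarray) -> float:
    """Upper bound on the number of tables visited by exact enumeration."""
    from math import comb

    c = t.shape[1]
    work = 1.0
    for rsum in t.sum(axis=1)[:-1]:
        work *= comb(int(rsum) + c - 1, c - 1)
    return work


def _fisher_enumerate(t: np.ndarray) -> float:
    """Exact two-sided Fisher p by enumerating all tables with the margins.

    Sums the probabilities of every table whose multivariate
    hypergeometric probability does not exceed the observed one (with a
    1e-7 relative slack for float equality, as in standard practice).
    """
    from scipy.special import gammaln

    rowsums = t.sum(axis=1)
    colsums = t.sum(axis=0).astype(int)
    r, c = t.shape
    logp_obs = _table_log_prob(t)
    const = float(
        gammaln(rowsums + 1).sum() + gammaln(colsums + 1).sum() - gammaln(t.sum() + 1)
    )
    total = 0.0

    def fill_row(i: int, rem_cols: np.ndarray, acc: float) -> None:
        nonlocal total
        if i == r - 1:
            lp = const + acc - float(gammaln(rem_cols + 1).sum())
            if lp <= logp_obs + 1e-7:
                total += np.exp(lp)
            return

        def fill_cell(j: int, remaining: int, rem_cols: np.ndarray, acc: float) -> None:
            if j == c - 1:
                if remaining <= rem_cols[c - 1]:
                    rc = rem_cols.copy()
                    rc[c - 1] -= remaining
                    fill_row(i + 1, rc, acc - float(gammaln(remaining + 1)))
                return
            for v in range(min(remaining, rem_cols[j]) + 1):
                rc = rem_cols.copy()
                rc[j] -= v
                fill_cell(j + 1, remaining - v, rc, acc - float(gammaln(v + 1)))

        fill_cell(0, int(rowsums[i]), rem_cols, acc)

    fill_row(0, colsums.copy(), 0.0)
    return min(total, 1.0)


def _fisher_montecarlo(t: np.ndarray, seed: int | None) -> float:
    """Permutation Monte-Carlo p for r x c Fisher, probability ordering."""
    rng = np.random.default_rng(seed)
    rows = np.repeat(np.arange(t.shape[0]), t.sum(axis=1))
    cols = np.repeat(np.arange(t.shape[1]), t.sum(axis=0))
    logp_obs = _table_log_prob(t)
    n_le = 0
    for _ in range(_MC_DRAWS):
        perm = rng.permutation(cols)
        sim = np.zeros_like(t)
        np.add.at(sim, (rows, perm), 1)
        if _table_log_prob(sim) <= logp_obs + 1e-12:
            n_le += 1
    return (1 + n_le) / (_MC_DRAWS + 1)


def _table_log_prob(t: np.ndarray) -> float:
    """log multivariate hypergeometric probability of a table given margins."""
    from scipy.special import gammaln

    n = t.sum()
    return float(
        gammaln(t.sum(axis=1) + 1).sum()
        + gammaln(t.sum(axis=0) + 1).sum()
        - gammaln(n + 1)
        - gammaln(t + 1).sum()
    )


def mann_whitney(x, y) -> TestResult:
    """Mann-Whitney U with tie-corrected normal approximation.

    Z is positive when the second sample (by convention the
    high-self-regulation profile) ranks higher; no continuity
    correction; two-sided normal p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise UnivariateError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)  # midranks
    r2 = ranks[n1:].sum()
    u2 = r2 - n2 * (n2 + 1) / 2.0  # U of the second sample
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        raise UnivariateError("all observations tied; Z is undefined")
    z = (u2 - n1 * n2 / 2.0) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(
        method="mann_whitney",
        statistic=float(z),
        p_value=float(min(p, 1.0)),
        notes={"U": float(u2), "tie_correction": tie_term > 0},
    )


def cronbach_alpha(items) -> float:
    """Cronbach's alpha of an n x k item-score matrix (variances with n-1)."""
    m = np.asarray(items, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2 or m.shape[0] < 2:
        raise UnivariateError("need an n x k matrix with n, k >= 2")
    k = m.shape[1]
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise UnivariateError("zero total-score variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - m.var(axis=0, ddof=1).sum() / total_var))


def spearman_matrix(cohort: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlations of the six scale totals."""
    cols = list(SCALE_RANGES)
    if len(cohort) < 3:
        raise UnivariateError("need at least 3 records for correlations")
    sub = cohort[cols]
    constant = [c for c in cols if sub[c].nunique() <= 1]
    if constant:
        raise UnivariateError(f"constant columns have undefined correlations: {constant}")
    rho = stats.spearmanr(sub.to_numpy()).statistic
    return pd.DataFrame(rho, index=cols, columns=cols)


def screen_sparse(
    counts: dict[str, np.ndarray | list],
    continuous: list[str] | tuple[str, ...] = (),
    threshold: int = 10,
) -> tuple[list[str], list[str]]:
    """Sparse-cell exclusion rule defining the multivariate candidate set.

    ``counts`` maps each categorical variable to its profile-by-level
    count table. A variable is excluded iff any cell falls below
    ``threshold``; continuous variables are always kept.
    """
    kept, excluded = [], []
    for name, table in counts.items():
        t = np.asarray(table)
        (excluded if (t < threshold).any() else kept).append(name)
    kept.extend(continuous)
    return kept, excluded


# --- report assembly -------------------------------------------------------

_EXPECTED_MIN_FOR_CHI2 = 5


def profile_crosstabs(labeled: pd.DataFrame, categorical: list[str]) -> dict[str, np.ndarray]:
    """Profile-by-level count tables (rows: low, high profile)."""
    out = {}
    for var in categorical:
        ct = pd.crosstab(labeled["profile"], labeled[var])
        ct = ct.reindex([LOW_LABEL, HIGH_LABEL])
        out[var] = ct.to_numpy()
    return out


def univariate_report(
    labeled: pd.DataFrame,
    categorical: list[str],
    continuous: list[str],
    seed: int | None = None,
) -> pd.DataFrame:
    """Profile-difference table: counts/medians, statistic, p, method.

    Categorical variables use the chi-square (Yates on 2x2) unless any
    expected count is below 5, in which case Fisher's exact test is
    reported. Continuous variables use Mann-Whitney with median (IQR)
    descriptives. Statistics are rounded to 2 decimals and p to 3 in the
    report, matching standard table style.
    """
    low = labeled[labeled["profile"] == LOW_LABEL]
    high = labeled[labeled["profile"] == HIGH_LABEL]
    rows = []
    for var in categorical:
        ct = pd.crosstab(labeled["profile"], labeled[var]).reindex([LOW_LABEL, HIGH_LABEL])
        t = ct.to_numpy()
        expected = stats.contingency.expected_freq(np.maximum(t, 0) + 0.0)
        if (expected < _EXPECTED_MIN_FOR_CHI2).any():
            res = fisher_exact(t, seed=seed)
        else:
            res = chi_square(t)
        for j, level in enumerate(ct.columns):
            rows.append(
                {
                    "variable": var,
                    "level": str(level),
                    "low": f"{t[0, j]}({100 * t[0, j] / t[0].sum():.1f})",
                    "high": f"{t[1, j]}({100 * t[1, j] / t[1].sum():.1f})",
                    "statistic": round(res.statistic, 2) if (j == 0 and res.statistic is not None) else np.nan,
                    "p": round(res.p_value, 3) if j == 0 else np.nan,
                    "method": res.method if j == 0 else "",
                }
            )
    for var in continuous:
        res = mann_whitney(low[var], high[var])
        rows.append(
            {
                "variable": var,
                "level": "median(P25,P75)",
                "low": _median_iqr(low[var]),
                "high": _median_iqr(high[var]),
                "statistic": round(res.statistic, 2),
                "p": round(res.p_value, 3),
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)


def _median_iqr(s: pd.Series) -> str:
    q1, med, q3 = s.quantile([0.25, 0.5, 0.75])
    return f"{med:g}({q1:g},{q3:g})"
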