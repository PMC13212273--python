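"""Bootstrap relaxed-LASSO stability selection for profile membership.

The inferential engine: across B bootstrap resamples of the labeled
cohort, an L1-penalized logistic regression with a cross-validated
penalty selects a variable subset, and an unpenalized refit on that
subset removes the shrinkage bias ("relaxed" LASSO). Aggregating the
replicates yields, per predictor, a selection frequency (majority vote
at a 50% threshold decides retention), the median odds ratio of the
refitted coefficients, a percentile 95% CI and an empirical p-value.

The L1 solver is IRLS with cyclic coordinate descent and
soft-thresholding (glmnet-style); the unpenalized refit is
Newton-Raphson with a separation guard. The outcome is coded 1 for the
low-self-regulation profile, so odds ratios below 1 are protective
against low-profile membership.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from .lpa import HIGH_LABEL, LOW_LABEL

logger = logging.getLogger(__name__)


class SelectionError(ValueError):
    pass


class ConvergenceError(SelectionError):
    def __init__(self, msg: str, trace: list[float] | None = None):
        super().__init__(msg)
        self.trace = trace or []


@dataclass
class DesignMatrix:
    """Coded predictor matrix with standardization bookkeeping.

    ``X`` holds the fitting-scale columns: binary predictors as 0/1 and
    continuous predictors z-scored on the fitting sample; ``raw`` keeps
    the uncoded values so bootstrap resamples can re-standardize.
    """

    X: np.ndarray
    raw: np.ndarray
    columns: list[str]
    is_binary: np.ndarray  # bool per column
    means: np.ndarray  # 0 for binary columns
    sds: np.ndarray  # 1 for binary columns


@dataclass
class LassoFit:
    lam: float
    intercept: float
    beta: np.ndarray
    active: np.ndarray  # indices of nonzero coefficients
    converged: bool
    objective: float


@dataclass
class RefitResult:
    intercept: float
    beta: np.ndarray  # on the fitting (standardized) scale
    se: np.ndarray
    converged: bool
    separated: bool


@dataclass
class ReplicateResult:
    replicate: int
    lam: float
    selected: list[str]
    coef_raw: dict[str, float]  # per-raw-unit log odds, selected predictors only
    separated: bool


@dataclass
class StabilitySummary:
    table: pd.DataFrame  # per predictor: frequency, median OR, CI, p, retained
    replicates: list[ReplicateResult] = field(default_factory=list)
    threshold: float = 0.5
    n_reps: int = 0


def build_design(
    labeled: pd.DataFrame,
    kept: list[str],
    binary_vars: list[str] | tuple[str, ...] | None = None,
    outcome_col: str = "profile",
) -> tuple[DesignMatrix, np.ndarray]:
    """Code the candidate predictors and the binary outcome.

    Binary predictors stay 0/1 (odds ratios per category); all others
    are z-scored on the fitting sample. Constant columns are dropped
    with a warning. Outcome: 1 = low self-regulators, 0 = high
    (reference).
    """
    prof = labeled[outcome_col].to_numpy()
    y = np.where(prof == LOW_LABEL, 1.0, np.where(prof == HIGH_LABEL, 0.0, np.nan))
    if np.isnan(y).any():
        raise SelectionError("unknown profile labels in outcome column")
    if y.min() == y.max():
        raise SelectionError("outcome has a single class; nothing to model")

    unknown = [v for v in kept if v not in labeled.columns]
    if unknown:
        raise SelectionError(f"unknown candidate variables: {unknown}")

    if binary_vars is None:
        binary_vars = [v for v in kept if set(np.unique(labeled[v])) <= {0, 1}]
    cols, raws, Xs, binmask, means, sds = [], [], [], [], [], []
    for v in kept:
        x = labeled[v].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            logger.warning("dropping constant predictor %r", v)
            continue
        is_bin = v in binary_vars
        if is_bin:
            m, s = 0.0, 1.0
            xc = x
        else:
            m, s = float(x.mean()), float(x.std(ddof=1))
            xc = (x - m) / s
        cols.append(v)
        raws.append(x)
        Xs.append(xc)
        binmask.append(is_bin)
        means.append(m)
        sds.append(s)
    if not cols:
        raise SelectionError("no usable predictors after coding")
    return (
        DesignMatrix(
            X=np.column_stack(Xs),
            raw=np.column_stack(raws),
            columns=cols,
            is_binary=np.array(binmask),
            means=np.array(means),
            sds=np.array(sds),
        ),
        y,
    )


# --- L1-penalized logistic regression -------------------------------------

_W_FLOOR = 1e-5


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every coefficient is exactly zero."""
    n = len(y)
    return float(np.abs(X.T @ (y - y.mean())).max() / n)


def _objective(X, y, intercept, beta, lam) -> float:
    eta = intercept + X @ beta
    # log(1 + e^eta) - y*eta, numerically stable
    dev = np.logaddexp(0.0, eta) - y * eta
    return float(dev.mean() + lam * np.abs(beta).sum())


@njit(cache=True)
def _cd_path_kernel(X, y, lams, tol, max_outer, max_inner, intercept0, beta0):
    """Coordinate-descent path over a decreasing penalty grid.

    IRLS outer iterations; on each quadratic approximation, cyclic
    coordinate descent with soft-thresholding and an unpenalized
    intercept. Solutions are warm-started from the previous grid point.
    Returns (intercepts, betas, converged) per grid value.
    """
    n, p = X.shape
    L = len(lams)
    betas = np.zeros((L, p))
    icpts = np.zeros(L)
    conv = np.zeros(L, dtype=np.bool_)
    beta = beta0.copy()
    intercept = intercept0
    for li in range(L):
        lam = lams[li]
        converged = False
        for _outer in range(max_outer):
            # IRLS weights and working response at current coefficients
            max_delta_outer = 0.0
            eta = intercept + X @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
            for i in range(n):
                if w[i] < 1e-5:
                    w[i] = 1e-5
            # working residual w*(z - eta) simplifies to y - mu exactly
            r = y - mu
            wx2 = np.zeros(p)
            for j in range(p):
                s = 0.0
                for i in range(n):
                    s += w[i] * X[i, j] * X[i, j]
                wx2[j] = s / n
            wsum = w.mean()
            for _inner in range(max_inner):
                max_delta = 0.0
                for j in range(p):
                    bj = beta[j]
                    rho = 0.0
                    for i in range(n):
                        rho += X[i, j] * r[i]
                    rho = rho / n + wx2[j] * bj
                    # tiny relative slack so |rho| == lam up to float
                    # rounding soft-thresholds to exactly zero
                    slack = lam + 1e-12 * (lam + 1.0)
                    if rho > slack:
                        bnew = (rho - lam) / wx2[j]
                    elif rho < -slack:
                        bnew = (rho + lam) / wx2[j]
                    else:
                        bnew = 0.0
                    if bnew != bj:
                        d = bnew - bj
                        for i in range(n):
                            r[i] -= w[i] * X[i, j] * d
                        beta[j] = bnew
                        if abs(d) > max_delta:
                            max_delta = abs(d)
                d0 = r.mean() / wsum
                if d0 != 0.0:
                    intercept += d0
                    for i in range(n):
                        r[i] -= w[i] * d0
                    if abs(d0) > max_delta:
                        max_delta = abs(d0)
                if max_delta > max_delta_outer:
                    max_delta_outer = max_delta
                if max_delta < tol:
                    break
            if max_delta_outer < tol:
                converged = True
                break
        betas[li] = beta
        icpts[li] = intercept
        conv[li] = converged
    return icpts, betas, conv


def lasso_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    warm: tuple[float, np.ndarray] | None = None,
    tol: float = 1e-7,
    max_outer: int = 100,
    max_inner: int = 200,
) -> LassoFit:
    """L1-penalized logistic regression at a single penalty value.

    Minimizes mean logistic deviance + lam * ||beta||_1 with an
    unpenalized intercept, by IRLS outer iterations and cyclic
    coordinate descent with soft-thresholding on the weighted quadratic
    approximation. Converged when the largest coefficient change in a
    full sweep falls below ``tol``.
    """
    if lam < 0:
        raise SelectionError("lambda must be non-negative")
    n, p = X.shape
    if warm is None:
        intercept = float(np.log(y.mean() / (1 - y.mean())))
        beta = np.zeros(p)
    else:
        intercept, beta = float(warm[0]), np.asarray(warm[1], dtype=float).copy()

    icpts, betas, conv = _cd_path_kernel(
        np.ascontiguousarray(X, dtype=np.float64),
        np.ascontiguousarray(y, dtype=np.float64),
        np.array([lam], dtype=np.float64),
        tol,
        max_outer,
        max_inner,
        intercept,
        beta,
    )
    obj = _objective(X, y, icpts[0], betas[0], lam)
    if not np.isfinite(obj):
        raise ConvergenceError("penalized objective diverged", [obj])
    return LassoFit(
        lam=lam,
        intercept=float(icpts[0]),
        beta=betas[0],
        active=np.flatnonzero(betas[0]),
        converged=bool(conv[0]),
        objective=obj,
    )


def lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    tol: float = 1e-7,
) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started solutions along a decreasing penalty grid.

    Returns (intercepts, betas) with one row per grid value.
    """
    p = X.shape[1]
    icpts, betas, _ = _cd_path_kernel(
        np.ascontiguousarray(X, dtype=np.float64),
        np.ascontiguousarray(y, dtype=np.float64),
        np.ascontiguousarray(grid, dtype=np.float64),
        tol,
        100,
        200,
        float(np.log(y.mean() / (1 - y.mean()))),
        np.zeros(p),
    )
    return icpts, betas


def kkt_violation(X: np.ndarray, y: np.ndarray, fit: LassoFit) -> float:
    """Largest violation of the first-order optimality conditions."""
    n = len(y)
    mu = expit(fit.intercept + X @ fit.beta)
    grad = X.T @ (mu - y) / n
    viol = 0.0
    for j in range(X.shape[1]):
        if fit.beta[j] != 0:
            viol = max(viol, abs(grad[j] + fit.lam * np.sign(fit.beta[j])))
        else:
            viol = max(viol, max(abs(grad[j]) - fit.lam, 0.0))
    viol = max(viol, abs(float(np.mean(mu - y))))  # intercept stationarity
    return viol


def lambda_grid(X: np.ndarray, y: np.ndarray, size: int = 100, ratio: float = 0.001) -> np.ndarray:
    lmax = lambda_max(X, y)
    return np.geomspace(lmax, ratio * lmax, size)


def _deviance(y: np.ndarray, eta: np.ndarray) -> float:
    mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
    return float(-2.0 * np.mean(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def cv_choose_lambda(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    grid: np.ndarray | None = None,
    seed: int | None = None,
    rule: str = "1se",
    path_tol: float = 1e-5,
) -> float:
    """Cross-validated penalty by held-out binomial deviance.

    Stratified K-fold CV over a path of penalties fitted with warm
    starts from the largest value down. ``rule="min"`` returns the
    deviance minimizer; ``rule="1se"`` (default) the largest penalty
    whose mean deviance is within one standard error of the minimum —
    the conservative choice that keeps noise variables out of the
    selected set. If a fold ends up single-class the split is redrawn
    with a new seed, at most 5 times.
    """
    if rule not in ("min", "1se"):
        raise SelectionError(f"unknown CV rule {rule!r}")
    if grid is None:
        grid = lambda_grid(X, y)
    grid = np.sort(np.atleast_1d(np.asarray(grid, dtype=float)))[::-1]
    if len(grid) == 1:
        return float(grid[0])
    rng = np.random.default_rng(seed)
    for _attempt in range(5):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31)))
        fold_dev = []
        ok = True
        for train, test in skf.split(X, y):
            ytr = y[train]
            if ytr.min() == ytr.max():
                ok = False
                break
            # held-out deviance is insensitive to coefficient precision,
            # so the CV path runs at a looser tolerance than final fits
            icpts, betas = lasso_path(X[train], ytr, grid, tol=path_tol)
            etas = icpts[:, None] + betas @ X[test].T  # L x n_test
            mu = np.clip(expit(etas), 1e-10, 1 - 1e-10)
            fold_dev.append(-2.0 * np.mean(y[test] * np.log(mu) + (1 - y[test]) * np.log(1 - mu), axis=1))
        if not ok:
            continue
        fold_dev = np.asarray(fold_dev)  # folds x L
        mean_dev = fold_dev.mean(axis=0)
        i_min = int(np.argmin(mean_dev))
        if rule == "min":
            return float(grid[i_min])
        se = fold_dev[:, i_min].std(ddof=1) / np.sqrt(len(fold_dev))
        within = np.flatnonzero(mean_dev <= mean_dev[i_min] + se)
        return float(grid[within[0]])  # grid is decreasing: first = largest penalty
    raise SelectionError("could not form stratified folds with both classes")


# --- unpenalized refit ----------------------------------------------------

_SEPARATION_BOUND = 15.0


def refit_unpenalized(X_S: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10) -> RefitResult:
    """Newton-Raphson logistic MLE on the selected columns.

    An empty selection yields the intercept-only model. Diverging
    coefficients (|beta| > 15 on the fitting scale) flag the fit as
    separated; such replicates are excluded from odds-ratio aggregation
    but still count toward selection frequency.
    """
    n = len(y)
    if X_S.size == 0:
        X_S = np.empty((n, 0))
    Xd = np.column_stack([np.ones(n), X_S])
    b = np.zeros(Xd.shape[1])
    b[0] = float(np.log(y.mean() / (1 - y.mean())))
    converged = separated = False
    for _ in range(max_iter):
        eta = Xd @ b
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        grad = Xd.T @ (y - mu)
        H = (Xd * w[:, None]).T @ Xd
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            separated = True
            break
        # step-halving keeps the likelihood non-decreasing
        ll0 = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        scale = 1.0
        for _h in range(30):
            bn = b + scale * step
            etan = Xd @ bn
            lln = float(np.sum(y * etan - np.logaddexp(0.0, etan)))
            if lln >= ll0 - 1e-12:
                break
            scale *= 0.5
        b = bn
        if np.abs(b[1:]).max(initial=0.0) > _SEPARATION_BOUND:
            separated = True
            break
        if np.abs(scale * step).max() < tol:
            converged = True
            break
    eta = Xd @ b
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-12, None)
    H = (Xd * w[:, None]).T @ Xd
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(Xd.shape[1], np.nan)
    return RefitResult(
        intercept=float(b[0]),
        beta=b[1:],
        se=se[1:],
        converged=converged,
        separated=separated,
    )


# --- bootstrap aggregation ------------------------------------------------


def _destandardize(beta_std: np.ndarray, sds: np.ndarray) -> np.ndarray:
    """Per-raw-unit coefficients: beta_raw = beta_std / sd (binary sd=1)."""
    return beta_std / sds


def bootstrap_relaxed_lasso(
    design: DesignMatrix,
    y: np.ndarray,
    B: int = 1000,
    threshold: float = 0.5,
    folds: int = 10,
    seed: int | None = None,
    grid_size: int = 100,
    rule: str = "1se",
) -> StabilitySummary:
    """Stability selection over B bootstrap relaxed-LASSO replicates.

    Each replicate resamples records with replacement, re-standardizes
    the continuous columns on the bootstrap sample, tunes the penalty by
    stratified CV, records the active set at the tuned penalty and the
    unpenalized refit coefficients on the raw predictor scale.
    Single-class bootstrap samples are redrawn (more than 5% redraws is
    an error). Deterministic given the seed.
    """
    if B < 1:
        raise SelectionError("B must be >= 1")
    n, p = design.raw.shape
    rng = np.random.default_rng(seed)
    replicates: list[ReplicateResult] = []
    redraws = 0
    for b in range(B):
        for _try in range(20):
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if yb.min() != yb.max():
                break
            redraws += 1
        else:
            raise SelectionError("could not draw a two-class bootstrap sample")
        raw_b = design.raw[idx]
        Xb = raw_b.copy()
        sds_b = np.ones(p)
        for j in range(p):
            if not design.is_binary[j]:
                m, s = raw_b[:, j].mean(), raw_b[:, j].std(ddof=1)
                if s == 0:
                    s = 1.0
                Xb[:, j] = (raw_b[:, j] - m) / s
                sds_b[j] = s
        lam = cv_choose_lambda(
            Xb, yb, folds=folds, grid=lambda_grid(Xb, yb, grid_size),
            seed=int(rng.integers(2**31)), rule=rule,
        )
        fit = lasso_logistic(Xb, yb, lam)
        S = fit.active
        refit = refit_unpenalized(Xb[:, S], yb)
        coef_raw = dict(zip([design.columns[j] for j in S], _destandardize(refit.beta, sds_b[S])))
        replicates.append(
            ReplicateResult(
                replicate=b,
                lam=lam,
                selected=[design.columns[j] for j in S],
                coef_raw=coef_raw,
                separated=refit.separated,
            )
        )
    if redraws > 0.05 * B:
        raise SelectionError(f"{redraws} single-class bootstrap redraws out of {B} replicates")
    if redraws:
        logger.warning("redrew %d single-class bootstrap samples", redraws)
    return _aggregate(design.columns, replicates, threshold, B)


def _aggregate(
    columns: list[str], replicates: list[ReplicateResult], threshold: float, B: int
) -> StabilitySummary:
    rows = []
    for name in columns:
        freq = sum(name in r.selected for r in replicates) / B
        betas = np.array([r.coef_raw[name] for r in replicates if name in r.coef_raw and not r.separated])
        if betas.size:
            ors = np.exp(betas)
            med = float(np.median(ors))
            lo, hi = np.percentile(ors, [2.5, 97.5])
            m = betas.size
            p_emp = max(2.0 * min((betas <= 0).mean(), (betas >= 0).mean()), 2.0 / m)
            p_emp = min(p_emp, 1.0)
        else:
            med = lo = hi = p_emp = np.nan
        rows.append(
            {
                "predictor": name,
                "frequency": freq,
                "median_or": med,
                "or_ci_low": float(lo) if betas.size else np.nan,
                "or_ci_high": float(hi) if betas.size else np.nan,
                "empirical_p": p_emp,
                "retained": freq >= threshold,
            }
        )
    table = pd.DataFrame(rows).sort_values("frequency", ascending=False, kind="stable").reset_index(drop=True)
    return StabilitySummary(table=table, replicates=replicates, threshold=threshold, n_reps=B)


def final_report(summary: StabilitySummary) -> pd.DataFrame:
    """Stability report: frequency, median OR, 95% CI, empirical p, retained.

    Odds ratios are oriented so outcome 1 is the low-self-regulation
    profile; an OR below 1 means the predictor protects against
    low-profile membership.
    """
    t = summary.table.copy()
    t["frequency"] = t["frequency"].round(3)
    for c in ("median_or", "or_ci_low", "or_ci_high"):
        t[c] = t[c].round(3)
    t["empirical_p"] = t["empirical_p"].round(4)
    return t
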