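"""Discrimination machinery: logistic models, AUC, ΔAUC with BCa bootstrap,
Youden-optimal cutpoints, and bootstrapped variance explained.

The ΔAUC question — how much does adding a covariate (here, the polygenic
score) to a nested baseline model improve discrimination — is answered by
refitting both models inside every bootstrap resample of participants and
summarizing the resampled ΔAUC with a bias-corrected and accelerated (BCa)
interval; the two-sided p value is the smallest level at which that interval
excludes zero.

The logistic solver is a compact Newton / iteratively-reweighted-least-
squares routine: bootstrap and jackknife loops refit hundreds of thousands
of small models, so the fit path is kept to a few dense linear solves.
It is cross-checked against an independent maximum-likelihood implementation
in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri

from .errors import ConvergenceError, ValidationError

DEFAULT_BOOT = 5000
_MAX_REDRAWS = 100


# ---------------------------------------------------------------------------
# Logistic regression (IRLS)
# ---------------------------------------------------------------------------

def _irls(y: np.ndarray, X: np.ndarray, max_iter: int = 50, tol: float = 1e-10) -> np.ndarray:
    """Newton-Raphson for logistic ML.  Raises ConvergenceError on divergence
    (the classic signature of complete separation)."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        W = mu * (1.0 - mu)
        # guard against a singular weighted Hessian
        W = np.maximum(W, 1e-12)
        grad = X.T @ (y - mu)
        H = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular Hessian in logistic fit") from exc
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            if np.max(np.abs(X @ beta)) > 30.0:
                raise ConvergenceError("fitted probabilities at 0/1: possible complete separation")
            return beta
        if np.max(np.abs(beta)) > 1e4:
            raise ConvergenceError("diverging coefficients: possible complete separation")
    raise ConvergenceError(f"logistic fit did not converge in {max_iter} iterations")


@dataclass(frozen=True)
class LogisticModel:
    """Fitted logistic model with Wald inference."""

    params: pd.Series
    cov: pd.DataFrame
    converged: bool
    n: int

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        Xm = _with_intercept(X).to_numpy(float)
        return expit(Xm @ self.params.to_numpy(float))

    def odds_ratios(self, level: float = 0.95) -> pd.DataFrame:
        """Per-covariate odds ratios with Wald confidence intervals."""
        se = np.sqrt(np.diag(self.cov.to_numpy(float)))
        z = ndtri(0.5 + level / 2.0)
        beta = self.params.to_numpy(float)
        wald_z = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
        return pd.DataFrame(
            {
                "coef": beta,
                "se": se,
                "or": np.exp(beta),
                "or_ci_low": np.exp(beta - z * se),
                "or_ci_high": np.exp(beta + z * se),
                "p": 2.0 * (1.0 - ndtr(np.abs(wald_z))),
            },
            index=self.params.index,
        )


def _with_intercept(X: pd.DataFrame) -> pd.DataFrame:
    if "const" in X.columns:
        return X
    out = X.copy()
    out.insert(0, "const", 1.0)
    return out


def fit_logistic(outcome, covariates: pd.DataFrame, max_iter: int = 50) -> LogisticModel:
    """Maximum-likelihood logistic regression of a binary outcome.

    An intercept is added automatically.  Complete separation raises
    ``ConvergenceError``; a single-class outcome raises ``ValidationError``.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome has a single class; both classes are required")
    X = _with_intercept(pd.DataFrame(covariates))
    if X.columns.duplicated().any():
        raise ValidationError("duplicate covariate names")
    Xm = X.to_numpy(float)
    if len(y) != len(Xm):
        raise ValidationError("outcome and covariates have different lengths")
    beta = _irls(y, Xm, max_iter=max_iter)
    mu = expit(Xm @ beta)
    W = np.maximum(mu * (1.0 - mu), 1e-12)
    cov = np.linalg.inv((Xm * W[:, None]).T @ Xm)
    return LogisticModel(
        params=pd.Series(beta, index=X.columns),
        cov=pd.DataFrame(cov, index=X.columns, columns=X.columns),
        converged=True,
        n=len(y),
    )


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def auc(scores, labels) -> float:
    """Rank-statistic (Mann-Whitney) AUC; tied scores count one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUC needs both classes present")
    from scipy.stats import rankdata

    r = rankdata(s)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _fit_auc(y: np.ndarray, Xm: np.ndarray) -> float:
    beta = _irls(y, Xm)
    return auc(Xm @ beta, y)


# ---------------------------------------------------------------------------
# BCa bootstrap
# ---------------------------------------------------------------------------

def bca_interval(
    theta_hat: float,
    boot_thetas: np.ndarray,
    jack_thetas: Optional[np.ndarray],
    level: float = 0.95,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap interval.

    With zero bias correction (half the replicates below the estimate) and
    zero acceleration (symmetric jackknife), this reduces exactly to the
    percentile interval.
    """
    t = np.sort(np.asarray(boot_thetas, dtype=float))
    B = t.size
    if B < 2:
        raise ValidationError("need at least 2 bootstrap replicates")
    if t[0] == t[-1]:  # degenerate bootstrap distribution
        return float(t[0]), float(t[0])
    prop = np.clip(np.mean(t < theta_hat), 1.0 / (2 * B), 1.0 - 1.0 / (2 * B))
    z0 = ndtri(prop)
    if jack_thetas is None:
        a = 0.0
    else:
        j = np.asarray(jack_thetas, dtype=float)
        d = j.mean() - j
        denom = (d**2).sum() ** 1.5
        a = float((d**3).sum() / (6.0 * denom)) if denom > 0 else 0.0
    alpha = 1.0 - level
    lo_hi = []
    for q in (alpha / 2.0, 1.0 - alpha / 2.0):
        zq = ndtri(q)
        adj = ndtr(z0 + (z0 + zq) / (1.0 - a * (z0 + zq)))
        lo_hi.append(float(np.quantile(t, np.clip(adj, 0.0, 1.0))))
    return lo_hi[0], lo_hi[1]


def _bca_pvalue(theta_hat, boot_thetas, jack_thetas) -> float:
    """Two-sided p by CI inversion: smallest alpha whose BCa interval excludes 0."""
    def excludes_zero(alpha: float) -> bool:
        lo, hi = bca_interval(theta_hat, boot_thetas, jack_thetas, level=1.0 - alpha)
        return lo > 0.0 or hi < 0.0

    lo_a, hi_a = 1e-6, 1.0 - 1e-6
    if not excludes_zero(hi_a):
        return 1.0
    if excludes_zero(lo_a):
        return float(lo_a)
    for _ in range(40):
        mid = 0.5 * (lo_a + hi_a)
        if excludes_zero(mid):
            hi_a = mid
        else:
            lo_a = mid
    return float(hi_a)


@dataclass(frozen=True)
class DeltaAucResult:
    auc_base: float
    auc_full: float
    delta: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int


def _resample_indices(rng, n, y, stratified):
    if not stratified:
        return rng.integers(0, n, n)
    idx1 = np.flatnonzero(y == 1)
    idx0 = np.flatnonzero(y == 0)
    return np.concatenate([rng.choice(idx1, idx1.size), rng.choice(idx0, idx0.size)])


def delta_auc_bca(
    outcome,
    covars_base: pd.DataFrame,
    covars_full: pd.DataFrame,
    n_boot: int = DEFAULT_BOOT,
    seed=None,
    stratified: bool = False,
    level: float = 0.95,
) -> DeltaAucResult:
    """ΔAUC of a full model over a strictly nested base model, with BCa CI.

    Both models are refit within every bootstrap resample of participant
    rows (unstratified by default); acceleration comes from leave-one-out
    jackknife refits.  Resamples with a single outcome class (or a
    non-convergent fit) are redrawn, up to 100 times per replicate.
    """
    y = np.asarray(outcome, dtype=float)
    Xb = _with_intercept(pd.DataFrame(covars_base))
    Xf = _with_intercept(pd.DataFrame(covars_full))
    base_cols, full_cols = set(Xb.columns), set(Xf.columns)
    if not base_cols <= full_cols:
        raise ValidationError("full covariate set must contain the base set")
    Xbm, Xfm = Xb.to_numpy(float), Xf.to_numpy(float)
    n = len(y)
    rng = np.random.default_rng(seed)

    auc_base = _fit_auc(y, Xbm)
    auc_full = _fit_auc(y, Xfm)
    delta = auc_full - auc_base

    boot = np.empty(n_boot)
    for b in range(n_boot):
        for attempt in range(_MAX_REDRAWS + 1):
            idx = _resample_indices(rng, n, y, stratified)
            yb = y[idx]
            if yb.min() == yb.max():
                continue
            try:
                boot[b] = _fit_auc(yb, Xfm[idx]) - _fit_auc(yb, Xbm[idx])
                break
            except ConvergenceError:
                continue
        else:
            raise ConvergenceError(f"bootstrap replicate {b}: no usable resample in {_MAX_REDRAWS} redraws")

    jack = np.empty(n)
    for i in range(n):
        idx = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        yi = y[idx]
        if yi.min() == yi.max():
            jack[i] = delta
            continue
        try:
            jack[i] = _fit_auc(yi, Xfm[idx]) - _fit_auc(yi, Xbm[idx])
        except ConvergenceError:
            jack[i] = delta

    ci_low, ci_high = bca_interval(delta, boot, jack, level=level)
    p = _bca_pvalue(delta, boot, jack)
    return DeltaAucResult(auc_base, auc_full, delta, ci_low, ci_high, p, n_boot)


# ---------------------------------------------------------------------------
# Youden cutpoint
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricCI:
    value: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class RocResult:
    """Single-variable classifier summary at the Youden-optimal threshold."""

    auc: MetricCI
    threshold: MetricCI
    sensitivity: MetricCI
    specificity: MetricCI
    ppv: MetricCI
    npv: MetricCI
    youden_j: float
    positive_low: bool
    n_boot: int


def _scan_threshold(s: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """Best threshold for rule 'positive if score >= t'; ties on J broken
    toward the higher-specificity (higher) threshold."""
    order = np.argsort(s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    n1 = y.sum()
    n0 = len(y) - n1
    uniq, first_idx = np.unique(s_sorted, return_index=True)
    # candidate thresholds: below min, midpoints between consecutive unique scores
    cands = np.concatenate([[uniq[0] - 1.0], (uniq[1:] + uniq[:-1]) / 2.0, [uniq[-1] + 1.0]])
    # positives/negatives with score >= t, via suffix sums at unique boundaries
    pos_cum = np.concatenate([[0.0], np.cumsum(y_sorted)])
    cnt_below = np.concatenate([first_idx, [len(s_sorted)]])  # rows strictly below each boundary
    tp = n1 - pos_cum[cnt_below]
    fp = (len(y) - cnt_below) - tp
    sens = tp / n1
    spec = (n0 - fp) / n0
    J = sens + spec - 1.0
    best = np.flatnonzero(J == J.max())
    k = best[np.argmax(spec[best])]
    t = float(cands[k])
    tpk, fpk = tp[k], fp[k]
    fnk, tnk = n1 - tpk, n0 - fpk
    ppv = tpk / (tpk + fpk) if (tpk + fpk) > 0 else np.nan
    npv = tnk / (tnk + fnk) if (tnk + fnk) > 0 else np.nan
    return t, float(sens[k]), float(spec[k]), float(ppv), float(npv)


def youden_cutpoint(
    scores,
    labels,
    positive_low: bool = False,
    n_boot: int = DEFAULT_BOOT,
    seed=None,
    level: float = 0.95,
) -> RocResult:
    """Youden-optimal threshold with sens/spec/PPV/NPV and percentile bootstrap CIs.

    ``positive_low=True`` declares that *low* scores indicate the positive
    class (e.g. a large negative height-minus-prediction gap flags a growth
    disorder); the reported threshold is then a 'positive if score <= t' rule.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes are required")
    sign = -1.0 if positive_low else 1.0

    def evaluate(si, yi):
        t, sens, spec, ppv, npv = _scan_threshold(sign * si, yi)
        return sign * t, sens, spec, ppv, npv

    t0, sens0, spec0, ppv0, npv0 = evaluate(s, y)
    auc0 = auc(sign * s, y)

    rng = np.random.default_rng(seed)
    n = len(y)
    stats = np.empty((n_boot, 6))
    for b in range(n_boot):
        for attempt in range(_MAX_REDRAWS + 1):
            idx = rng.integers(0, n, n)
            if y[idx].min() != y[idx].max():
                break
        else:
            raise ValidationError("could not draw a two-class bootstrap resample")
        tb, seb, spb, ppb, npb = evaluate(s[idx], y[idx])
        stats[b] = (tb, seb, spb, ppb, npb, auc(sign * s[idx], y[idx]))

    alpha = 1.0 - level

    def pct(col, value):
        v = stats[:, col]
        v = v[~np.isnan(v)]
        return MetricCI(value, float(np.quantile(v, alpha / 2)), float(np.quantile(v, 1 - alpha / 2)))

    return RocResult(
        auc=pct(5, auc0),
        threshold=pct(0, t0),
        sensitivity=pct(1, sens0),
        specificity=pct(2, spec0),
        ppv=pct(3, ppv0),
        npv=pct(4, npv0),
        youden_j=sens0 + spec0 - 1.0,
        positive_low=positive_low,
        n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# Variance explained
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class R2Result:
    r2: float
    ci_low: float
    ci_high: float
    n_boot: int


def _ols_r2(y: np.ndarray, Xm: np.ndarray) -> float:
    beta, _, rank, _ = np.linalg.lstsq(Xm, y, rcond=None)
    if rank < Xm.shape[1]:
        raise ValidationError("rank-deficient design in R^2 computation")
    resid = y - Xm @ beta
    sst = ((y - y.mean()) ** 2).sum()
    if sst == 0:
        raise ValidationError("response has zero variance")
    return float(1.0 - (resid**2).sum() / sst)


def r2_bootstrap(response, predictors: pd.DataFrame, n_boot: int = DEFAULT_BOOT, seed=None, level: float = 0.95) -> R2Result:
    """OLS R^2 with a percentile bootstrap CI over participant-row resamples."""
    y = np.asarray(response, dtype=float)
    X = _with_intercept(pd.DataFrame(predictors))
    Xm = X.to_numpy(float)
    if len(y) <= Xm.shape[1] + 1:
        raise ValidationError("too few observations for the number of predictors")
    r2 = _ols_r2(y, Xm)
    rng = np.random.default_rng(seed)
    n = len(y)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            boot[b] = _ols_r2(y[idx], Xm[idx])
        except ValidationError:
            boot[b] = np.nan
    boot = boot[~np.isnan(boot)]
    alpha = 1.0 - level
    return R2Result(r2, float(np.quantile(boot, alpha / 2)), float(np.quantile(boot, 1 - alpha / 2)), n_boot)
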