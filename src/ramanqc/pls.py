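"""Partial least squares regression with VIP selection and outlier diagnostics.

This is a from-scratch single-response PLS1 implementation in the NIPALS
style: each latent variable (LV) is extracted as the weight direction
maximising covariance between the (deflated) spectral matrix and the
response, followed by deflation of both blocks.  On top of the factor
extraction the module provides

* the composite regression vector and per-LV explained X-variance,
* Variable Importance in Projection (VIP) scores and VIP-threshold
  variable selection,
* contiguous-block cross-validation with per-fold re-centering,
* a parsimony rule for choosing the LV count,
* Hotelling's T-squared / Q-residual outlier diagnostics with 95%
  confidence limits,
* the evaluation metrics R-squared, RMSE and Bias.

All routines operate on plain numpy arrays; preprocessing (smoothing,
baseline removal) happens upstream, while centering of X and y is handled
*inside* ``fit_pls`` and the CV loop so that no held-out statistic ever
leaks into a fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "NumericalDegeneracyError",
    "PLSFit",
    "BlockCVResult",
    "OutlierDiagnostics",
    "EvaluationReport",
    "fit_pls",
    "predict",
    "scores_for",
    "vip_scores",
    "select_variables",
    "block_cv",
    "choose_n_lv",
    "outlier_diagnostics",
    "regression_metrics",
    "prediction_slope",
    "split_train_test",
]

_EPS = 1e-12


class NumericalDegeneracyError(ValueError):
    """The data admit no (further) latent variable."""


@dataclass
class PLSFit:
    """A fitted PLS1 model.

    Factor matrices follow the usual NIPALS notation: ``weights`` W
    (p x A, unit columns), ``loadings`` P (p x A), ``y_loadings`` q (A,),
    ``scores`` T (n x A, mutually orthogonal).  ``coef`` is the composite
    regression vector B = W (P'W)^-1 q on centered data; predictions are
    ``(X - x_mean) @ B + y_mean``.
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray
    loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    coef: np.ndarray
    explained_x_variance_pct: np.ndarray
    n_samples: int
    train_q: np.ndarray | None = None  # per-training-row residual SSQ (Q statistic)

    @property
    def rotation(self) -> np.ndarray:
        """R = W (P'W)^-1, mapping centered X to scores (T = Xc R)."""
        a = self.loadings.T @ self.weights
        return self.weights @ np.linalg.inv(a)


def fit_pls(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSFit:
    """Fit a PLS1 model with ``n_lv`` latent variables.

    X and y are centered internally (means stored on the fit).  Extraction
    stops early, with a warning, if the residual covariance vanishes (e.g.
    noiseless data whose structure is exhausted); a zero-variance X raises
    :class:`NumericalDegeneracyError` immediately.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X rows and y length differ")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    max_lv = min(n - 1, p)
    if n_lv > max_lv:
        raise ValueError(f"n_lv={n_lv} exceeds rank limit min(n-1, p)={max_lv}")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    ssx_total = float(np.sum(Xc**2))
    if ssx_total < _EPS:
        raise NumericalDegeneracyError("X has zero variance")

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    q = np.zeros(n_lv)
    explained = np.zeros(n_lv)

    Xd, yd = Xc.copy(), yc.copy()
    extracted = 0
    for a in range(n_lv):
        w = Xd.T @ yd
        wn = float(np.linalg.norm(w))
        if wn < _EPS * max(1.0, float(np.linalg.norm(yc))):
            warnings.warn(
                f"residual covariance vanished after {extracted} LV(s); truncating",
                RuntimeWarning,
                stacklevel=2,
            )
            break
        w /= wn
        t = Xd @ w
        tt = float(t @ t)
        if tt < _EPS:
            warnings.warn(
                f"degenerate score at LV {a + 1}; truncating", RuntimeWarning, stacklevel=2
            )
            break
        pvec = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd -= np.outer(t, pvec)
        yd = yd - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pvec, t, qa
        explained[a] = 100.0 * tt * float(pvec @ pvec) / ssx_total
        extracted += 1

    if extracted == 0:
        raise NumericalDegeneracyError("no latent variable could be extracted")
    W, P, T, q = W[:, :extracted], P[:, :extracted], T[:, :extracted], q[:extracted]
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSFit(
        n_lv=extracted,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        loadings=P,
        y_loadings=q,
        scores=T,
        coef=coef,
        explained_x_variance_pct=explained[:extracted],
        n_samples=n,
        train_q=np.sum(Xd**2, axis=1),  # final deflation residual = off-model variance
    )


def predict(fit: PLSFit, X: np.ndarray) -> np.ndarray:
    """Predict the response: centered X times the regression vector, plus the training mean."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != fit.x_mean.size:
        raise ValueError(
            f"X has {X.shape[1]} variables, model expects {fit.x_mean.size}"
        )
    return (X - fit.x_mean) @ fit.coef + fit.y_mean


def scores_for(fit: PLSFit, X: np.ndarray) -> np.ndarray:
    """Project (new) samples into the latent-variable score space."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != fit.x_mean.size:
        raise ValueError("variable count mismatch")
    return (X - fit.x_mean) @ fit.rotation


def vip_scores(fit: PLSFit) -> np.ndarray:
    """Variable Importance in Projection, one score per retained variable.

    ``VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a )`` with
    ``SSY_a = q_a^2 t_a't_a`` the response variance captured by LV a.  By
    construction the squared scores average to one (``sum VIP^2 = p``).
    """
    p = fit.weights.shape[0]
    ssy = fit.y_loadings**2 * np.sum(fit.scores**2, axis=0)
    total = float(ssy.sum())
    if total < _EPS:
        raise NumericalDegeneracyError("model explains no response variance; VIP undefined")
    wnorm2 = np.sum(fit.weights**2, axis=0)
    wnorm2 = np.where(wnorm2 < _EPS, 1.0, wnorm2)
    contrib = (fit.weights**2 / wnorm2) @ ssy
    return np.sqrt(p * contrib / total)


def select_variables(vip: np.ndarray, threshold: float = 0.8) -> np.ndarray:
    """Boolean keep-mask dropping variables with VIP below ``threshold``.

    A single selection pass; callers refit once on the retained variables.
    Raises if the threshold would drop every variable.
    """
    vip = np.asarray(vip, dtype=float)
    keep = vip >= threshold
    if not np.any(keep):
        raise ValueError(f"VIP threshold {threshold} drops all {vip.size} variables")
    return keep


# ---------------------------------------------------------------------------
# cross-validation and model-size selection


@dataclass
class BlockCVResult:
    """Contiguous-block CV curves: one entry per candidate LV count (1..A).

    ``rmsecv_se`` is the standard error of the per-fold RMSE at each LV
    count (fold-to-fold scatter / sqrt(n_folds)), used by the
    one-standard-error model-size rule.
    """

    n_lv_grid: np.ndarray
    rmsecv: np.ndarray
    r2_cv: np.ndarray
    bias_cv: np.ndarray
    predictions: np.ndarray  # (n_samples, A) held-out predictions
    fold_bounds: list[tuple[int, int]]
    rmsecv_se: np.ndarray | None = None

    def curve_at(self, n_lv: int) -> tuple[float, float, float]:
        i = int(n_lv) - 1
        return float(self.rmsecv[i]), float(self.r2_cv[i]), float(self.bias_cv[i])


def _coef_path(fit: PLSFit) -> np.ndarray:
    """Regression vectors for every truncation 1..n_lv of a fitted model, (p, A)."""
    p, A = fit.weights.shape
    out = np.zeros((p, A))
    for a in range(1, A + 1):
        Wa, Pa, qa = fit.weights[:, :a], fit.loadings[:, :a], fit.y_loadings[:a]
        out[:, a - 1] = Wa @ np.linalg.solve(Pa.T @ Wa, qa)
    return out


def block_cv(
    X: np.ndarray, y: np.ndarray, n_lv_max: int, block_size: int = 10
) -> BlockCVResult:
    """Cross-validate over contiguous sample blocks in stored order.

    Samples are partitioned, in their given order, into consecutive blocks
    of ``block_size`` (the last block may be short).  For each fold, the
    centering statistics and the PLS factors are re-estimated on the
    retained rows only, and the held-out block is predicted at every LV
    count up to ``n_lv_max`` (truncated, with a warning, to the per-fold
    rank limit).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if not (1 <= block_size < n):
        raise ValueError(f"block_size must be in [1, n-1]; got {block_size} for n={n}")
    bounds = [(i, min(i + block_size, n)) for i in range(0, n, block_size)]
    fold_max = min(min(n - (hi - lo) for lo, hi in bounds) - 1, X.shape[1])
    if n_lv_max > fold_max:
        warnings.warn(
            f"n_lv_max={n_lv_max} exceeds the per-fold rank limit {fold_max}; truncating",
            RuntimeWarning,
            stacklevel=2,
        )
        n_lv_max = fold_max
    if n_lv_max < 1:
        raise ValueError("no latent variable fits within the fold rank limit")

    preds = np.empty((n, n_lv_max))
    for lo, hi in bounds:
        mask = np.ones(n, dtype=bool)
        mask[lo:hi] = False
        fit = fit_pls(X[mask], y[mask], n_lv_max)
        path = _coef_path(fit)  # (p, extracted)
        Xc_out = X[lo:hi] - fit.x_mean
        block_pred = Xc_out @ path + fit.y_mean
        if fit.n_lv < n_lv_max:  # early truncation: extend with the last column
            pad = np.repeat(block_pred[:, -1:], n_lv_max - fit.n_lv, axis=1)
            block_pred = np.hstack([block_pred, pad])
        preds[lo:hi] = block_pred

    sst = float(np.sum((y - y.mean()) ** 2))
    resid = preds - y[:, None]
    rmsecv = np.sqrt(np.mean(resid**2, axis=0))
    bias = np.mean(resid, axis=0)
    r2 = 1.0 - np.sum(resid**2, axis=0) / sst if sst > 0 else np.full(n_lv_max, np.nan)
    fold_rmse = np.array([np.sqrt(np.mean(resid[lo:hi] ** 2, axis=0)) for lo, hi in bounds])
    se = (
        fold_rmse.std(axis=0, ddof=1) / np.sqrt(len(bounds))
        if len(bounds) > 1
        else np.zeros(n_lv_max)
    )
    return BlockCVResult(
        n_lv_grid=np.arange(1, n_lv_max + 1),
        rmsecv=rmsecv,
        r2_cv=r2,
        bias_cv=bias,
        predictions=preds,
        fold_bounds=bounds,
        rmsecv_se=se,
    )


def choose_n_lv(
    rmsecv: np.ndarray, rel_tol: float = 0.02, se: np.ndarray | None = None
) -> int:
    """Parsimonious LV count from an RMSECV curve.

    With ``se`` given (the per-LV standard error of the fold RMSEs), the
    one-standard-error rule is applied: the smallest LV count whose RMSECV
    lies within one SE of the global minimum.  Without ``se``, a relative
    band is used instead: within ``rel_tol`` (default 2%) of the minimum.
    Ties break toward fewer LVs; a flat curve therefore yields 1.
    """
    rmsecv = np.asarray(rmsecv, dtype=float)
    if rmsecv.size < 1:
        raise ValueError("empty CV curve")
    i = int(np.argmin(rmsecv))
    if se is not None:
        threshold = rmsecv[i] + float(np.asarray(se, dtype=float)[i])
    else:
        threshold = rmsecv[i] * (1.0 + rel_tol)
    ok = rmsecv <= threshold + _EPS
    return int(np.argmax(ok)) + 1


# ---------------------------------------------------------------------------
# outlier diagnostics


@dataclass
class OutlierDiagnostics:
    """Hotelling's T-squared and Q-residual per sample, with 95% limits.

    T-squared measures leverage within the score space (distance from the
    model centre scaled by the training score variances); Q is the residual
    sum of squares orthogonal to the model plane.  A sample is flagged when
    either statistic exceeds its limit.
    """

    t2: np.ndarray
    q: np.ndarray
    t2_limit: float
    q_limit: float
    flagged: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.flagged = (self.t2 > self.t2_limit) | (self.q > self.q_limit)


def outlier_diagnostics(
    fit: PLSFit, X: np.ndarray, confidence: float = 0.95
) -> OutlierDiagnostics:
    """T-squared / Q diagnostics of ``X`` against a fitted model.

    The T-squared limit uses the usual F-distribution scaling
    ``A(n-1)(n+1) / (n(n-A)) * F_{1-a}(A, n-A)`` with n the training-sample
    count and A the LV count.  The Q limit uses a moment-based chi-squared
    approximation (g * chi2_h) fitted to the training residuals.
    """
    if fit.n_lv < 1:
        raise ValueError("diagnostics need at least one latent variable")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    t_new = scores_for(fit, X)
    s2 = np.var(fit.scores, axis=0, ddof=1)
    s2 = np.where(s2 < _EPS, np.inf, s2)  # a dead LV contributes no leverage
    t2 = np.sum(t_new**2 / s2, axis=1)
    resid = (X - fit.x_mean) - t_new @ fit.loadings.T
    qvals = np.sum(resid**2, axis=1)

    n, A = fit.n_samples, fit.n_lv
    if n > A:
        f_crit = stats.f.ppf(confidence, A, n - A)
        t2_limit = A * (n - 1) * (n + 1) / (n * (n - A)) * f_crit
    else:
        t2_limit = np.inf
    # training residuals define the Q reference distribution
    q_train = fit.train_q if fit.train_q is not None else qvals
    m = float(np.mean(q_train))
    v = float(np.var(q_train, ddof=1)) if q_train.size > 1 else 0.0
    if m > _EPS and v > _EPS:
        g = v / (2.0 * m)
        h = 2.0 * m * m / v
        q_limit = g * stats.chi2.ppf(confidence, h)
    else:
        q_limit = m  # degenerate residuals: limit collapses to their level
    return OutlierDiagnostics(t2=t2, q=qvals, t2_limit=float(t2_limit), q_limit=float(q_limit))


# ---------------------------------------------------------------------------
# evaluation metrics


def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    """(R-squared, RMSE, Bias) of predictions against references.

    ``R^2 = 1 - SSE/SST``, ``RMSE = sqrt(mean((yhat - y)^2))``,
    ``Bias = mean(yhat - y)``.  RMSE always bounds |Bias|.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0:
        raise ValueError("empty split")
    if y_true.size != y_pred.size:
        raise ValueError("length mismatch")
    resid = y_pred - y_true
    rmse = float(np.sqrt(np.mean(resid**2)))
    bias = float(np.mean(resid))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else np.nan
    return r2, rmse, bias


def prediction_slope(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Slope of the least-squares line of predicted on reference values."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size < 2:
        raise ValueError("slope needs at least two points")
    return float(np.polyfit(y_true, y_pred, 1)[0])


@dataclass
class EvaluationReport:
    """R-squared / RMSE / Bias for the calibration, cross-validation and
    prediction splits, plus the predicted-vs-reference slope."""

    n_lv: int
    r2_cal: float
    rmsec: float
    bias_cal: float
    r2_cv: float
    rmsecv: float
    bias_cv: float
    r2_pred: float
    rmsep: float
    bias_pred: float
    slope: float

    def to_dict(self) -> dict[str, float]:
        return {
            "n_lv": self.n_lv,
            "r2_cal": self.r2_cal,
            "rmsec": self.rmsec,
            "bias_cal": self.bias_cal,
            "r2_cv": self.r2_cv,
            "rmsecv": self.rmsecv,
            "bias_cv": self.bias_cv,
            "r2_pred": self.r2_pred,
            "rmsep": self.rmsep,
            "bias_pred": self.bias_pred,
            "slope": self.slope,
        }


# ---------------------------------------------------------------------------
# train/test splitting


def split_train_test(
    dose_labels: np.ndarray,
    n_test: int = 15,
    per_dose_quota: tuple[int, int] = (2, 4),
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test split honouring a per-dose test quota.

    Each dose level contributes between ``per_dose_quota[0]`` and
    ``per_dose_quota[1]`` test samples; the returned index arrays are
    disjoint, exhaustive and sorted (so both splits preserve acquisition
    order, which contiguous-block CV relies on).
    """
    dose_labels = np.asarray(dose_labels)
    n = dose_labels.size
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    qmin, qmax = per_dose_quota
    levels = list(dict.fromkeys(dose_labels.tolist()))  # preserve order
    if n_test < 1 or n_test >= n:
        raise ValueError("n_test must be in [1, n-1]")
    if not (qmin * len(levels) <= n_test <= qmax * len(levels)):
        raise ValueError(
            f"quota {per_dose_quota} over {len(levels)} levels cannot produce n_test={n_test}"
        )
    counts = {lv: qmin for lv in levels}
    remaining = n_test - qmin * len(levels)
    while remaining > 0:
        open_levels = [lv for lv in levels if counts[lv] < qmax]
        lv = open_levels[int(rng.integers(len(open_levels)))]
        counts[lv] += 1
        remaining -= 1
    test_idx: list[int] = []
    for lv in levels:
        members = np.flatnonzero(dose_labels == lv)
        if counts[lv] > members.size:
            raise ValueError(f"level {lv!r} has only {members.size} samples for quota {counts[lv]}")
        pick = rng.choice(members, size=counts[lv], replace=False)
        test_idx.extend(int(i) for i in pick)
    test = np.array(sorted(test_idx), dtype=int)
    train = np.setdiff1d(np.arange(n), test)
    return train, test
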