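"""Spectral preprocessing: replicate averaging, smoothing, baseline removal, centering.

The chain mirrors standard Raman chemometric practice and is applied in a
fixed order: replicate spectra are averaged to one spectrum per tablet, the
averaged spectrum is smoothed with a Savitzky-Golay filter, a baseline
estimated by asymmetric least squares (AsLS) is subtracted, and finally the
spectra matrix is mean-centered column-wise.  Smoothing and baseline removal
are per-spectrum operations; centering is the only *fitted* statistic, so it
is estimated on training rows only and re-applied, unchanged, to new
samples.

Savitzky-Golay edges use scipy's ``mode="interp"``: the terminal half-window
is filled from a polynomial fitted to the last full window, i.e. polynomial
extrapolation on the terminal window.  A requested even window (the
conventional "30 point" setting) is widened to the nearest larger odd count
by :func:`nearest_odd_window`; callers are expected to log that adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

__all__ = [
    "Spectrum",
    "PreprocessParams",
    "AxisMismatchError",
    "NotFittedError",
    "nearest_odd_window",
    "average_replicates",
    "savitzky_golay",
    "asls_baseline",
    "MeanCenterer",
    "SpectralPreprocessor",
]


class AxisMismatchError(ValueError):
    """Spectra do not share a common wavenumber axis."""


class NotFittedError(RuntimeError):
    """A fitted statistic was applied before fitting."""


@dataclass(frozen=True)
class Spectrum:
    """One measurement: a strictly increasing wavenumber axis plus intensities."""

    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", y)
        if w.ndim != 1 or y.ndim != 1 or w.size != y.size:
            raise ValueError("wavenumbers and intensities must be 1-D of equal length")
        if w.size >= 2 and np.any(np.diff(w) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(y))):
            raise ValueError("spectrum contains non-finite values")


@dataclass
class PreprocessParams:
    """Preprocessing settings plus the fitted centering statistics.

    ``sg_window`` must be odd and larger than ``sg_polyorder``; the AsLS
    asymmetry weight ``asls_p`` lies in (0, 1) and the smoothness penalty
    ``asls_lambda`` is positive.  ``center_mean`` (and ``y_mean``) are filled
    at fit time.
    """

    sg_window: int = 31
    sg_polyorder: int = 2
    asls_lambda: float = 1e5
    asls_p: float = 1e-3
    asls_iterations: int = 10
    baseline_correction: bool = True
    smoothing: bool = True
    center_mean: np.ndarray | None = field(default=None, repr=False)
    y_mean: float | None = None

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0:
            raise ValueError(
                f"sg_window must be odd, got {self.sg_window}; "
                "adjust even requests upstream with nearest_odd_window()"
            )
        if self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must exceed sg_polyorder")
        if not (0.0 < self.asls_p < 1.0):
            raise ValueError("asls_p must lie in (0, 1)")
        if self.asls_lambda <= 0:
            raise ValueError("asls_lambda must be positive")
        if self.asls_iterations < 1:
            raise ValueError("asls_iterations must be >= 1")


def nearest_odd_window(window: int) -> int:
    """Round an even window request up to the nearest odd point count."""
    window = int(window)
    if window < 3:
        raise ValueError("window must be >= 3 points")
    return window if window % 2 == 1 else window + 1


def average_replicates(spectra: list[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of replicate spectra sharing one axis."""
    if len(spectra) == 0:
        raise ValueError("need at least one spectrum")
    axis = spectra[0].wavenumbers
    for s in spectra[1:]:
        if s.wavenumbers.size != axis.size or not np.allclose(
            s.wavenumbers, axis, rtol=0.0, atol=1e-9
        ):
            raise AxisMismatchError("replicates do not share a common wavenumber axis")
    stack = np.vstack([s.intensities for s in spectra])
    return Spectrum(axis.copy(), stack.mean(axis=0))


def savitzky_golay(y: np.ndarray, window: int = 31, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing of one spectrum (or matrix rows).

    Local least-squares polynomial smoothing; output length equals input
    length; edges are filled by evaluating a polynomial fitted on the
    terminal window (``mode="interp"``).  ``window`` must be odd and larger
    than ``polyorder`` but no larger than the spectrum.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[-1]
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if window > n:
        raise ValueError(f"window {window} exceeds spectrum length {n}")
    return savgol_filter(y, window_length=window, polyorder=polyorder, mode="interp", axis=-1)


def asls_baseline(
    y: np.ndarray, lam: float = 1e5, p: float = 1e-3, iterations: int = 10
) -> np.ndarray:
    """Asymmetric least-squares baseline (Eilers-style).

    Minimises ``sum_i w_i (y_i - z_i)^2 + lam * sum (d2 z)^2`` by iteratively
    reweighted penalised least squares: after each solve, points above the
    current baseline get weight ``p`` and points at or below it weight
    ``1 - p``.  With ``p`` small the baseline hugs the lower envelope,
    ignoring positive peaks.  Returns the baseline; subtraction is the
    caller's (trivial) step.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("asls_baseline expects a 1-D spectrum")
    if not np.all(np.isfinite(y)):
        raise ValueError("intensities must be finite")
    if not (0.0 < p < 1.0) or lam <= 0 or iterations < 1:
        raise ValueError("invalid AsLS parameters")
    n = y.size
    if n < 3:
        return y.copy()
    # second-difference operator, (n-2) x n
    d = sparse.eye(n, format="csc")
    d = d[1:] - d[:-1]
    d = d[1:] - d[:-1]
    penalty = lam * (d.T @ d)
    w = np.ones(n)
    z = y.copy()
    for _ in range(iterations):
        a = sparse.diags(w) + penalty
        z = spsolve(a.tocsc(), w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z


class MeanCenterer:
    """Column mean-centering fitted on training rows only.

    Test rows are centered with the *training* means, never their own, so no
    statistic of the test set leaks into the model.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "MeanCenterer":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise NotFittedError("MeanCenterer used before fit()")
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.mean_.size:
            raise ValueError("column count does not match fitted means")
        return X - self.mean_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


class SpectralPreprocessor:
    """The fixed preprocessing chain: smooth -> baseline-subtract -> center.

    Smoothing and baseline estimation are stateless per-spectrum transforms;
    only the column means are fitted.  ``transform_spectra`` applies the
    stateless part (usable before fitting); ``fit``/``apply_center`` handle
    the fitted part.
    """

    def __init__(self, params: PreprocessParams | None = None) -> None:
        self.params = params if params is not None else PreprocessParams()
        self._centerer = MeanCenterer()

    def transform_spectra(self, X: np.ndarray) -> np.ndarray:
        """Smooth and baseline-correct each row; no fitted statistics involved."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        p = self.params
        out = np.empty_like(X)
        for i, row in enumerate(X):
            y = savitzky_golay(row, p.sg_window, p.sg_polyorder) if p.smoothing else row
            if p.baseline_correction:
                y = y - asls_baseline(y, p.asls_lambda, p.asls_p, p.asls_iterations)
            out[i] = y
        return out

    def fit_center(self, X_transformed: np.ndarray) -> "SpectralPreprocessor":
        self._centerer.fit(X_transformed)
        self.params.center_mean = self._centerer.mean_
        return self

    def apply_center(self, X_transformed: np.ndarray) -> np.ndarray:
        if self.params.center_mean is None:
            raise NotFittedError("centering applied before fit_center()")
        self._centerer.mean_ = np.asarray(self.params.center_mean, dtype=float)
        return self._centerer.transform(X_transformed)

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        z = self.transform_spectra(X)
        self.fit_center(z)
        return self.apply_center(z)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Full chain for new samples using the stored training means."""
        return self.apply_center(self.transform_spectra(X))
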