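"""Model/Results surface for the Raman content calibration.

:class:`RamanContentModel` is constructed from tablet-level spectra and
reference contents (e.g. a :class:`~ramanqc.synth.CalibrationStudy` or data
read from disk); calling :meth:`~RamanContentModel.fit` runs the full
calibration workflow —

1. smooth and baseline-correct every spectrum,
2. contiguous-block cross-validation over candidate latent-variable counts,
3. pick the LV count by the within-2%-of-minimum parsimony rule (unless a
   count is forced),
4. fit the PLS model, score variables by VIP, drop those below the
   threshold in one pass, refit, and re-run CV on the retained variables,
5. compute training-set outlier diagnostics —

and returns a :class:`RamanContentResults` carrying the estimates, the CV
curves before and after variable selection, diagnostics, a ``summary()``
table, ``predict()`` for new spectra and an ``evaluate()`` that produces
the calibration/CV/prediction metric report.  Results serialise to a
single JSON artifact so that predict-only runs are reproducible bit for
bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from . import pls
from .preprocess import PreprocessParams, SpectralPreprocessor, nearest_odd_window

if TYPE_CHECKING:  # pragma: no cover
    from .synth import CalibrationStudy

__all__ = ["RamanContentModel", "RamanContentResults"]

logger = logging.getLogger("ramanqc")

ARTIFACT_VERSION = 1


class RamanContentModel:
    """PLS calibration relating preprocessed Raman spectra to API content.

    Parameters
    ----------
    spectra : (n_samples, n_points) array
        Replicate-averaged raw spectra, one row per tablet, in acquisition
        order (contiguous-block CV folds follow this order).
    wavenumbers : (n_points,) array
        Common wavenumber axis in cm^-1.
    content_mg : (n_samples,) array
        Reference API content per tablet (mg), e.g. from an HPLC assay.
    dose_mg : array, optional
        Dose label per tablet; kept for splitting and plotting.
    preprocess : PreprocessParams, optional
        Smoothing / baseline settings.  An even Savitzky-Golay window is
        adjusted to the nearest odd count (logged).
    n_lv : int, optional
        Force this LV count instead of selecting one from the CV curve.
    n_lv_max : int
        Largest LV count scanned by cross-validation.
    cv_block_size : int
        Contiguous-block CV block size.
    vip_threshold : float
        Variables with VIP below this are dropped (single pass + refit);
        set to 0 to disable selection.
    """

    def __init__(
        self,
        spectra: np.ndarray,
        wavenumbers: np.ndarray,
        content_mg: np.ndarray,
        dose_mg: np.ndarray | None = None,
        sample_ids: list[str] | None = None,
        *,
        preprocess: PreprocessParams | None = None,
        n_lv: int | None = None,
        n_lv_max: int = 10,
        cv_block_size: int = 10,
        vip_threshold: float = 0.8,
        lv_selection_tol: float = 0.02,
    ) -> None:
        self.spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
        self.wavenumbers = np.asarray(wavenumbers, dtype=float)
        self.content_mg = np.asarray(content_mg, dtype=float).ravel()
        if self.spectra.shape[0] != self.content_mg.size:
            raise ValueError("spectra rows and content length differ")
        if self.spectra.shape[1] != self.wavenumbers.size:
            raise ValueError("spectra columns and wavenumber axis differ")
        self.dose_mg = None if dose_mg is None else np.asarray(dose_mg, dtype=float).ravel()
        self.sample_ids = sample_ids or [f"S{i + 1:03d}" for i in range(self.content_mg.size)]
        self.preprocess_params = preprocess if preprocess is not None else PreprocessParams()
        self.n_lv = n_lv
        self.n_lv_max = int(n_lv_max)
        self.cv_block_size = int(cv_block_size)
        self.vip_threshold = float(vip_threshold)
        self.lv_selection_tol = float(lv_selection_tol)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_study(
        cls, study: "CalibrationStudy", indices: np.ndarray | None = None, **kwargs
    ) -> "RamanContentModel":
        """Build a model from a synthetic calibration study (optionally a subset of rows)."""
        idx = np.arange(study.spectra.shape[0]) if indices is None else np.asarray(indices)
        return cls(
            spectra=study.spectra[idx],
            wavenumbers=study.wavenumbers,
            content_mg=study.reference_content_mg[idx],
            dose_mg=study.dose_mg[idx],
            sample_ids=[study.sample_ids[i] for i in idx],
            **kwargs,
        )

    @classmethod
    def from_tables(
        cls, spectra_df, metadata_df, **kwargs
    ) -> "RamanContentModel":
        """Build a model from the package's delimited-text tables.

        ``spectra_df``: first column ``wavenumber_cm-1``, one column per
        tablet.  ``metadata_df``: columns ``tablet_id``, ``dose_mg`` and
        either ``reference_content_mg`` or ``reference_content_pct``.
        """
        wn = spectra_df.iloc[:, 0].to_numpy(dtype=float)
        ids = list(spectra_df.columns[1:])
        X = spectra_df.iloc[:, 1:].to_numpy(dtype=float).T
        meta = metadata_df.set_index("tablet_id").loc[ids]
        dose = meta["dose_mg"].to_numpy(dtype=float)
        if "reference_content_mg" in meta.columns:
            y = meta["reference_content_mg"].to_numpy(dtype=float)
        else:
            y = meta["reference_content_pct"].to_numpy(dtype=float) / 100.0 * dose
        return cls(spectra=X, wavenumbers=wn, content_mg=y, dose_mg=dose, sample_ids=ids, **kwargs)

    # -- fitting ----------------------------------------------------------

    def fit(self) -> "RamanContentResults":
        params = self.preprocess_params
        if params.sg_window % 2 == 0:  # defensive; PreprocessParams already rejects
            adjusted = nearest_odd_window(params.sg_window)
            logger.info("SG window adjusted %d -> %d (odd count required)", params.sg_window, adjusted)
            params.sg_window = adjusted

        prep = SpectralPreprocessor(params)
        Z = prep.transform_spectra(self.spectra)  # stateless part; centering is per-fit
        y = self.content_mg

        n_lv_max = min(self.n_lv_max, Z.shape[0] - 1, Z.shape[1])
        cv_pre = pls.block_cv(Z, y, n_lv_max, self.cv_block_size)
        n_lv = self.n_lv if self.n_lv is not None else pls.choose_n_lv(
            cv_pre.rmsecv, self.lv_selection_tol, se=cv_pre.rmsecv_se
        )
        logger.info("latent variables: %d (scanned 1..%d)", n_lv, cv_pre.n_lv_grid[-1])

        fit_full = pls.fit_pls(Z, y, n_lv)
        vip_full = pls.vip_scores(fit_full)
        if self.vip_threshold > 0:
            mask = pls.select_variables(vip_full, self.vip_threshold)
        else:
            mask = np.ones(Z.shape[1], dtype=bool)
        n_dropped = int(np.count_nonzero(~mask))
        logger.info(
            "VIP selection: dropped %d of %d variables (threshold %.2f)",
            n_dropped, mask.size, self.vip_threshold,
        )
        if n_dropped > 0:
            fit_sel = pls.fit_pls(Z[:, mask], y, min(n_lv, int(mask.sum())))
            cv_post = pls.block_cv(Z[:, mask], y, n_lv_max, self.cv_block_size)
        else:
            fit_sel, cv_post = fit_full, cv_pre

        prep.fit_center(Z)  # stored for reporting; PLS keeps its own means
        diag = pls.outlier_diagnostics(fit_sel, Z[:, mask])
        logger.info(
            "training outliers flagged: %s",
            [self.sample_ids[i] for i in np.flatnonzero(diag.flagged)] or "none",
        )
        return RamanContentResults(
            model=self,
            preprocessor=prep,
            fit=fit_sel,
            fit_all_variables=fit_full,
            variable_mask=mask,
            vip=vip_full,
            n_lv=fit_sel.n_lv,
            cv_pre_selection=cv_pre,
            cv=cv_post,
            train_diagnostics=diag,
        )


@dataclass
class RamanContentResults:
    """Fitted calibration: estimates, CV curves, diagnostics, predictions."""

    model: RamanContentModel
    preprocessor: SpectralPreprocessor
    fit: pls.PLSFit
    fit_all_variables: pls.PLSFit
    variable_mask: np.ndarray
    vip: np.ndarray
    n_lv: int
    cv_pre_selection: pls.BlockCVResult
    cv: pls.BlockCVResult
    train_diagnostics: pls.OutlierDiagnostics
    _fitted_values: np.ndarray | None = field(default=None, repr=False)

    # -- core accessors ---------------------------------------------------

    @property
    def regression_vector(self) -> np.ndarray:
        """Regression coefficients on the retained variables (mg per count)."""
        return self.fit.coef

    @property
    def explained_x_variance_pct(self) -> np.ndarray:
        return self.fit.explained_x_variance_pct

    @property
    def fittedvalues(self) -> np.ndarray:
        if self._fitted_values is None:
            Z = self.preprocessor.transform_spectra(self.model.spectra)
            self._fitted_values = pls.predict(self.fit, Z[:, self.variable_mask])
        return self._fitted_values

    def predict(self, spectra: np.ndarray) -> np.ndarray:
        """Predict API content (mg) for raw averaged spectra on the model's axis."""
        spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
        if spectra.shape[1] != self.model.wavenumbers.size:
            raise ValueError("spectra do not match the model's wavenumber axis")
        Z = self.preprocessor.transform_spectra(spectra)
        return pls.predict(self.fit, Z[:, self.variable_mask])

    def diagnostics(self, spectra: np.ndarray) -> pls.OutlierDiagnostics:
        """Hotelling's T-squared / Q-residual diagnostics for new spectra."""
        Z = self.preprocessor.transform_spectra(np.atleast_2d(np.asarray(spectra, float)))
        return pls.outlier_diagnostics(self.fit, Z[:, self.variable_mask])

    # -- evaluation -------------------------------------------------------

    def evaluate(
        self, test_spectra: np.ndarray | None = None, test_content_mg: np.ndarray | None = None
    ) -> pls.EvaluationReport:
        """Metric report over the calibration, CV and (optional) prediction splits."""
        y = self.model.content_mg
        r2c, rmsec, bc = pls.regression_metrics(y, self.fittedvalues)
        rmsecv, r2cv, bcv = self.cv.curve_at(self.n_lv)
        if test_spectra is not None:
            if test_content_mg is None:
                raise ValueError("test_content_mg required with test_spectra")
            y_test = np.asarray(test_content_mg, dtype=float).ravel()
            yhat = self.predict(test_spectra)
            r2p, rmsep, bp = pls.regression_metrics(y_test, yhat)
            slope = pls.prediction_slope(y_test, yhat)
        else:
            r2p = rmsep = bp = float("nan")
            slope = pls.prediction_slope(y, self.fittedvalues)
        return pls.EvaluationReport(
            n_lv=self.n_lv,
            r2_cal=r2c, rmsec=rmsec, bias_cal=bc,
            r2_cv=r2cv, rmsecv=rmsecv, bias_cv=bcv,
            r2_pred=r2p, rmsep=rmsep, bias_pred=bp,
            slope=slope,
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        m = self.model
        rep = self.evaluate()
        lines = [
            "Raman PLS content calibration",
            "=" * 46,
            f"samples (training)      {m.content_mg.size}",
            f"variables retained      {int(self.variable_mask.sum())} / {self.variable_mask.size}"
            f"  (VIP < {m.vip_threshold:g} dropped)",
            f"latent variables        {self.n_lv}",
            "explained X variance    "
            + ", ".join(f"LV{i + 1}: {v:.1f}%" for i, v in enumerate(self.explained_x_variance_pct)),
            f"SG window / polyorder   {m.preprocess_params.sg_window} / {m.preprocess_params.sg_polyorder}",
            f"AsLS lambda / p / iter  {m.preprocess_params.asls_lambda:g} / "
            f"{m.preprocess_params.asls_p:g} / {m.preprocess_params.asls_iterations}",
            "-" * 46,
            f"R2 (cal)    {rep.r2_cal:8.4f}    RMSEC  {rep.rmsec:8.4f} mg",
            f"R2 (CV)     {rep.r2_cv:8.4f}    RMSECV {rep.rmsecv:8.4f} mg",
            f"Bias (cal)  {rep.bias_cal:8.4f} mg  Bias (CV) {rep.bias_cv:8.4f} mg",
            f"outliers flagged (train)  {int(self.train_diagnostics.flagged.sum())}",
        ]
        return "\n".join(lines)

    # -- plotting ---------------------------------------------------------

    def plot_prediction(self, test_spectra=None, test_content_mg=None, ax=None):
        """Predicted vs reference content; optionally overlays a test set."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = self.model.content_mg
        ax.plot(y, self.fittedvalues, "o", label="training", color="tab:blue")
        if test_spectra is not None:
            yhat = self.predict(test_spectra)
            ax.plot(test_content_mg, yhat, "s", label="test", color="tab:red")
        lims = [min(y.min(), 0.0), y.max() * 1.05]
        ax.plot(lims, lims, "k--", lw=1, label="ideal")
        ax.set_xlabel("reference content (mg)")
        ax.set_ylabel("predicted content (mg)")
        ax.legend()
        return ax

    def plot_scores(self, ax=None):
        """Scores on LV1/LV2 coloured by reference content."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        T = self.fit.scores
        c = self.model.content_mg
        sc = ax.scatter(T[:, 0], T[:, 1] if T.shape[1] > 1 else np.zeros_like(T[:, 0]), c=c)
        ax.figure.colorbar(sc, ax=ax, label="content (mg)")
        ax.set_xlabel("LV1 score")
        ax.set_ylabel("LV2 score")
        return ax

    # -- serialisation ----------------------------------------------------

    def save(self, path) -> None:
        """Write the portable JSON model artifact (everything predict needs)."""
        m = self.model
        p = m.preprocess_params
        payload = {
            "format": "ramanqc-model",
            "version": ARTIFACT_VERSION,
            "wavenumbers": m.wavenumbers.tolist(),
            "variable_mask": self.variable_mask.astype(int).tolist(),
            "vip": self.vip.tolist(),
            "preprocess": {
                "sg_window": p.sg_window,
                "sg_polyorder": p.sg_polyorder,
                "asls_lambda": p.asls_lambda,
                "asls_p": p.asls_p,
                "asls_iterations": p.asls_iterations,
                "baseline_correction": p.baseline_correction,
                "smoothing": p.smoothing,
            },
            "pls": {
                "n_lv": self.fit.n_lv,
                "x_mean": self.fit.x_mean.tolist(),
                "y_mean": self.fit.y_mean,
                "weights": self.fit.weights.tolist(),
                "loadings": self.fit.loadings.tolist(),
                "y_loadings": self.fit.y_loadings.tolist(),
                "scores": self.fit.scores.tolist(),
                "coef": self.fit.coef.tolist(),
                "explained_x_variance_pct": self.fit.explained_x_variance_pct.tolist(),
                "n_samples": self.fit.n_samples,
                "train_q": self.fit.train_q.tolist() if self.fit.train_q is not None else None,
            },
            "fold_bounds": [list(b) for b in self.cv.fold_bounds],
            "sample_ids": m.sample_ids,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @staticmethod
    def load_predictor(path) -> "LoadedPredictor":
        """Load a saved artifact for predict/diagnose-only use."""
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format") != "ramanqc-model":
            raise ValueError("not a ramanqc model artifact")
        return LoadedPredictor(payload)


class LoadedPredictor:
    """Predict-only view of a serialised calibration artifact."""

    def __init__(self, payload: dict) -> None:
        self.wavenumbers = np.asarray(payload["wavenumbers"], dtype=float)
        self.variable_mask = np.asarray(payload["variable_mask"], dtype=bool)
        pp = payload["preprocess"]
        self.preprocessor = SpectralPreprocessor(
            PreprocessParams(
                sg_window=pp["sg_window"],
                sg_polyorder=pp["sg_polyorder"],
                asls_lambda=pp["asls_lambda"],
                asls_p=pp["asls_p"],
                asls_iterations=pp["asls_iterations"],
                baseline_correction=pp.get("baseline_correction", True),
                smoothing=pp.get("smoothing", True),
            )
        )
        pl = payload["pls"]
        self.fit = pls.PLSFit(
            n_lv=pl["n_lv"],
            x_mean=np.asarray(pl["x_mean"], dtype=float),
            y_mean=float(pl["y_mean"]),
            weights=np.asarray(pl["weights"], dtype=float),
            loadings=np.asarray(pl["loadings"], dtype=float),
            y_loadings=np.asarray(pl["y_loadings"], dtype=float),
            scores=np.asarray(pl["scores"], dtype=float),
            coef=np.asarray(pl["coef"], dtype=float),
            explained_x_variance_pct=np.asarray(pl["explained_x_variance_pct"], dtype=float),
            n_samples=int(pl["n_samples"]),
            train_q=None if pl["train_q"] is None else np.asarray(pl["train_q"], dtype=float),
        )

    def predict(self, spectra: np.ndarray) -> np.ndarray:
        spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
        if spectra.shape[1] != self.wavenumbers.size:
            raise ValueError("spectra do not match the artifact's wavenumber axis")
        Z = self.preprocessor.transform_spectra(spectra)
        return pls.predict(self.fit, Z[:, self.variable_mask])

    def diagnostics(self, spectra: np.ndarray) -> pls.OutlierDiagnostics:
        Z = self.preprocessor.transform_spectra(np.atleast_2d(np.asarray(spectra, float)))
        return pls.outlier_diagnostics(self.fit, Z[:, self.variable_mask])
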