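"""End-to-end study orchestration: configuration, run directory, logging.

:func:`run_study` chains the whole workflow — simulate a calibration
campaign, split it 50/15 with a 2-4 per-dose test quota, fit the Raman PLS
calibration (preprocessing, block CV, LV choice, VIP selection, outlier
diagnostics), evaluate on the held-out tablets, and run the pharmacopoeial
batch checks on a simulated QC batch — writing every artifact into one run
directory:

* ``manifest.json`` — config + seed + package version (re-run recipe),
* ``spectra.csv`` / ``metadata.csv`` / ``dissolution.csv`` — simulated inputs,
* ``model.json`` — the portable calibration artifact,
* ``evaluation.csv`` — R2 / RMSE / Bias for calibration, CV and prediction,
* ``predictions.csv`` — per-test-tablet predicted vs reference content,
* ``qc_mass.csv`` / ``qc_content.csv`` / ``qc_dissolution.csv`` — QC reports,
* ``run.log`` — seed, SG window adjustment, AsLS settings, fold
  boundaries, variables dropped by VIP, samples flagged as outliers.

Identical config + seed give byte-identical numerical outputs (the log and
manifest carry no timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, pharmaqc, pls
from .model import RamanContentModel
from .preprocess import PreprocessParams, nearest_odd_window
from .synth import SyntheticBatchConfig, generate_calibration_study, generate_qc_batch

__all__ = ["ModelBlock", "QCBlock", "RunConfig", "run_study"]

logger = logging.getLogger("ramanqc")


@dataclass
class ModelBlock:
    """Calibration-model settings for a run."""

    n_lv: int | None = None  # None: choose from the CV curve
    n_lv_max: int = 10
    cv_block_size: int = 10
    vip_threshold: float = 0.8
    lv_selection_tol: float = 0.02
    n_test: int = 15
    test_quota_min: int = 2
    test_quota_max: int = 4

    def __post_init__(self) -> None:
        if self.n_lv_max < 1 or self.cv_block_size < 1:
            raise ValueError("n_lv_max and cv_block_size must be >= 1")
        if self.vip_threshold < 0:
            raise ValueError("vip_threshold must be >= 0")
        if not (1 <= self.test_quota_min <= self.test_quota_max):
            raise ValueError("invalid test quota range")


@dataclass
class QCBlock:
    """Simulated QC-batch settings (defaults: a 400 mg batch of 48 tablets
    with 1.62% weight RSD, a 10-tablet content batch at 106% of label with
    2% RSD, and a 6-vessel dissolution run with first-order release)."""

    nominal_mass_mg: float = 400.0
    n_tablets_mass: int = 48
    mass_rsd_pct: float = 1.62
    n_tablets_content: int = 10
    content_mean_pct: float = 106.0
    content_rsd_pct: float = 2.0
    n_tablets_dissolution: int = 6
    dissolution_rate_per_min: float = 0.1
    dissolution_rate_rsd_pct: float = 10.0
    dissolution_checkpoint_min: float = 30.0
    dissolution_threshold_pct: float = 80.0

    def __post_init__(self) -> None:
        if self.nominal_mass_mg <= 0:
            raise ValueError("nominal mass must be positive")
        for name in ("n_tablets_mass", "n_tablets_content", "n_tablets_dissolution"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class RunConfig:
    """Validated configuration for one reproducible study run.

    Every block is validated by its own type's invariants at construction,
    before any computation starts.  The top-level ``seed`` drives all
    randomness (the synthetic block's own seed is overridden).
    """

    synth: SyntheticBatchConfig = field(default_factory=SyntheticBatchConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    model: ModelBlock = field(default_factory=ModelBlock)
    qc: QCBlock = field(default_factory=QCBlock)
    seed: int = 1

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        synth_kwargs = dict(d.get("synth", {}))
        # manifest round-trips store signature names, not objects; defaults apply
        for key in ("api_signature", "excipient_signatures"):
            if isinstance(synth_kwargs.get(key), (str, list)):
                synth_kwargs.pop(key)
        prep_kwargs = dict(d.get("preprocess", {}))
        if "sg_window" in prep_kwargs and int(prep_kwargs["sg_window"]) % 2 == 0:
            requested = int(prep_kwargs["sg_window"])
            prep_kwargs["sg_window"] = nearest_odd_window(requested)
            logger.info("SG window adjusted %d -> %d (odd count required)",
                        requested, prep_kwargs["sg_window"])
        return cls(
            synth=SyntheticBatchConfig(**synth_kwargs),
            preprocess=PreprocessParams(**prep_kwargs),
            model=ModelBlock(**d.get("model", {})),
            qc=QCBlock(**d.get("qc", {})),
            seed=int(d.get("seed", 1)),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "synth": self.synth.to_dict(),
            "preprocess": {
                k: v
                for k, v in dataclasses.asdict(self.preprocess).items()
                if k not in ("center_mean", "y_mean")
            },
            "model": dataclasses.asdict(self.model),
            "qc": dataclasses.asdict(self.qc),
            "seed": self.seed,
        }


def _attach_log(run_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(run_dir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))  # no timestamps
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler


def run_study(config: RunConfig, output_dir) -> dict:
    """Run the full simulate -> calibrate -> evaluate -> QC workflow.

    Returns a dict with the in-memory results (study, split, results,
    report, QC outcomes) and writes all artifacts under ``output_dir``.
    """
    run_dir = Path(output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = _attach_log(run_dir)
    try:
        logger.info("seed %d", config.seed)
        seeds = np.random.SeedSequence(config.seed).generate_state(3) % (2**31)
        synth_cfg = dataclasses.replace(config.synth, seed=int(seeds[0]))
        study = generate_calibration_study(synth_cfg)
        logger.info(
            "simulated %d tablets (%d levels x %d), %d replicates each",
            synth_cfg.n_tablets, len(synth_cfg.dose_levels_mg),
            synth_cfg.tablets_per_level, synth_cfg.replicates_per_tablet,
        )
        io.write_spectra(run_dir / "spectra.csv", study.wavenumbers, study.spectra, study.sample_ids)
        io.write_batch_metadata(
            run_dir / "metadata.csv",
            study.sample_ids,
            study.dose_mg,
            synth_cfg.tablet_mass_mg,
            study.reference_content_pct,
            study.reference_content_mg,
        )

        mb = config.model
        train_idx, test_idx = pls.split_train_test(
            study.dose_mg,
            n_test=mb.n_test,
            per_dose_quota=(mb.test_quota_min, mb.test_quota_max),
            rng=np.random.default_rng(int(seeds[1])),
        )
        logger.info("split: %d training / %d test tablets", train_idx.size, test_idx.size)

        model = RamanContentModel.from_study(
            study,
            indices=train_idx,
            preprocess=config.preprocess,
            n_lv=mb.n_lv,
            n_lv_max=mb.n_lv_max,
            cv_block_size=mb.cv_block_size,
            vip_threshold=mb.vip_threshold,
            lv_selection_tol=mb.lv_selection_tol,
        )
        results = model.fit()
        logger.info("CV fold boundaries: %s", results.cv.fold_bounds)
        results.save(run_dir / "model.json")

        test_X = study.spectra[test_idx]
        test_y = study.reference_content_mg[test_idx]
        report = results.evaluate(test_X, test_y)
        pd.DataFrame([report.to_dict()]).to_csv(run_dir / "evaluation.csv", index=False)
        yhat = results.predict(test_X)
        diag = results.diagnostics(test_X)
        pd.DataFrame(
            {
                "tablet_id": [study.sample_ids[i] for i in test_idx],
                "dose_mg": study.dose_mg[test_idx],
                "reference_content_mg": test_y,
                "predicted_content_mg": yhat,
                "t2": diag.t2,
                "q": diag.q,
                "outlier_flag": diag.flagged,
            }
        ).to_csv(run_dir / "predictions.csv", index=False)
        logger.info(
            "test outliers flagged: %s",
            [study.sample_ids[i] for i in test_idx[np.flatnonzero(diag.flagged)]] or "none",
        )

        # pharmacopoeial QC on a simulated batch
        qc = config.qc
        qrng = np.random.default_rng(int(seeds[2]))
        batch = generate_qc_batch(
            nominal_mass_mg=qc.nominal_mass_mg,
            n_tablets=max(qc.n_tablets_mass, qc.n_tablets_content, qc.n_tablets_dissolution),
            mass_rsd_pct=qc.mass_rsd_pct,
            content_mean_pct=qc.content_mean_pct,
            content_rsd_pct=qc.content_rsd_pct,
            dissolution_rate_per_min=qc.dissolution_rate_per_min,
            dissolution_rate_rsd_pct=qc.dissolution_rate_rsd_pct,
            rng=qrng,
        )
        masses = batch.tablet_masses_mg[: qc.n_tablets_mass]
        mass_res = pharmaqc.mass_uniformity(masses, qc.nominal_mass_mg)
        pd.DataFrame(
            {
                "tablet_id": [f"M{i + 1:02d}" for i in range(masses.size)],
                "mass_mg": masses,
                "deviation_pct": mass_res.deviation_pct,
                "passed": mass_res.passed,
            }
        ).to_csv(run_dir / "qc_mass.csv", index=False)
        logger.info(
            "mass uniformity: accuracy %.1f%% (limit +/-%g%%)",
            mass_res.dosing_accuracy_pct, mass_res.threshold_used_pct,
        )

        contents = batch.assayed_content_pct[: qc.n_tablets_content]
        cu = pharmaqc.acceptance_value(contents)
        pd.DataFrame([{
            "n": cu.n, "mean_pct": cu.mean_pct, "s_pct": cu.s_pct, "k": cu.k,
            "m_reference": cu.m_reference, "av": cu.av, "av_rounded": cu.av_rounded,
            "passed": cu.passed,
        }]).to_csv(run_dir / "qc_content.csv", index=False)
        logger.info("content uniformity: AV %.2f (rounded %d), pass=%s", cu.av, cu.av_rounded, cu.passed)

        diss_ids = [f"V{i + 1}" for i in range(qc.n_tablets_dissolution)]
        profiles = batch.dissolution_pct[: qc.n_tablets_dissolution]
        io.write_dissolution(run_dir / "dissolution.csv", diss_ids, batch.dissolution_times_min, profiles)
        diss = pharmaqc.dissolution_compliance(
            batch.dissolution_times_min, profiles,
            checkpoint_min=qc.dissolution_checkpoint_min,
            threshold_pct=qc.dissolution_threshold_pct,
        )
        pd.DataFrame(
            {
                "tablet_id": diss_ids,
                "released_at_checkpoint_pct": diss.released_at_checkpoint_pct,
                "passed": diss.tablet_passed,
            }
        ).to_csv(run_dir / "qc_dissolution.csv", index=False)
        logger.info("dissolution: batch pass=%s at %g min / %g%%",
                    diss.batch_passed, diss.checkpoint_min, diss.threshold_pct)

        manifest = {
            "package": "ramanqc",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "outputs": sorted(p.name for p in run_dir.iterdir() if p.name != "manifest.json"),
        }
        with open(run_dir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

        return {
            "study": study,
            "train_idx": train_idx,
            "test_idx": test_idx,
            "results": results,
            "report": report,
            "mass": mass_res,
            "content": cu,
            "dissolution": diss,
            "run_dir": run_dir,
        }
    finally:
        logger.removeHandler(handler)
        handler.close()
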