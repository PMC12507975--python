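"""Orchestration: run directories, reproducibility, I/O round trips, CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import ramanqc as rq
from ramanqc import io
from ramanqc.cli import main as cli_main
from ramanqc.model import RamanContentResults

NOISE_FREE = {
    "synth": {
        "noise_sd": 0.0,
        "baseline_amplitude": 0.0,
        "high_dose_extra_cv": 0.0,
        "content_rsd_pct": 0.0,
        "assay_rsd_pct": 0.0,
        "api_sampling_rsd_pct": 0.0,
        "excipient_rsd_pct": 5.0,
    },
    # no drift is simulated, so the baseline step has nothing to remove
    "preprocess": {"baseline_correction": False},
    "model": {"n_lv": 3, "vip_threshold": 0.0},
    "seed": 3,
}


@pytest.fixture(scope="module")
def run_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    result = rq.run_study(rq.RunConfig(seed=11), out)
    return out, result


class TestRunStudy:
    def test_outputs_present(self, run_dir):
        out, _ = run_dir
        for name in (
            "manifest.json", "spectra.csv", "metadata.csv", "model.json",
            "evaluation.csv", "predictions.csv", "qc_mass.csv",
            "qc_content.csv", "qc_dissolution.csv", "dissolution.csv", "run.log",
        ):
            assert (out / name).exists(), name

    def test_report_schema_covers_all_splits(self, run_dir):
        out, _ = run_dir
        df = pd.read_csv(out / "evaluation.csv")
        for col in ("r2_cal", "r2_cv", "r2_pred", "rmsec", "rmsecv", "rmsep",
                    "bias_cal", "bias_cv", "bias_pred", "slope", "n_lv"):
            assert col in df.columns

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        rq.run_study(rq.RunConfig(seed=21), a)
        rq.run_study(rq.RunConfig(seed=21), b)
        for name in ("evaluation.csv", "predictions.csv", "spectra.csv", "model.json"):
            assert (a / name).read_bytes() == (b / name).read_bytes(), name

    def test_noise_free_limit_predicts_exactly(self, tmp_path):
        cfg = rq.RunConfig.from_dict(NOISE_FREE)
        result = rq.run_study(cfg, tmp_path / "nf")
        assert result["report"].rmsep < 1e-6

    def test_log_records_key_events(self, run_dir):
        out, _ = run_dir
        log = (out / "run.log").read_text()
        assert "seed 11" in log
        assert "fold boundaries" in log
        assert "VIP selection" in log
        assert "outliers flagged" in log

    def test_manifest_round_trips_into_config(self, run_dir):
        out, _ = run_dir
        manifest = json.loads((out / "manifest.json").read_text())
        cfg = rq.RunConfig.from_dict(manifest["config"])
        assert cfg.seed == 11
        assert cfg.synth.tablets_per_level == 13


class TestConfig:
    def test_even_sg_window_adjusted(self):
        cfg = rq.RunConfig.from_dict({"preprocess": {"sg_window": 30}})
        assert cfg.preprocess.sg_window == 31

    def test_invalid_block_rejected_before_compute(self):
        with pytest.raises(ValueError):
            rq.RunConfig.from_dict({"synth": {"tablets_per_level": 0}})
        with pytest.raises(ValueError):
            rq.RunConfig.from_dict({"model": {"test_quota_min": 5, "test_quota_max": 2}})

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump({"seed": 9, "synth": {"noise_sd": 1.5}}))
        cfg = rq.RunConfig.from_yaml(path)
        assert cfg.seed == 9
        assert cfg.synth.noise_sd == 1.5


class TestIORoundTrips:
    def test_spectra_table(self, tmp_path, default_study):
        path = tmp_path / "spectra.csv"
        io.write_spectra(path, default_study.wavenumbers, default_study.spectra,
                         default_study.sample_ids)
        wn, X, ids = io.read_spectra(path)
        np.testing.assert_array_equal(wn, default_study.wavenumbers)
        np.testing.assert_array_equal(X, default_study.spectra)
        assert ids == default_study.sample_ids

    def test_metadata_table(self, tmp_path, default_study):
        path = tmp_path / "meta.csv"
        io.write_batch_metadata(
            path, default_study.sample_ids, default_study.dose_mg, 400.0,
            default_study.reference_content_pct, default_study.reference_content_mg,
        )
        df = io.read_batch_metadata(path)
        np.testing.assert_array_equal(df["dose_mg"].to_numpy(), default_study.dose_mg)
        np.testing.assert_array_equal(
            df["reference_content_mg"].to_numpy(), default_study.reference_content_mg
        )

    def test_dissolution_table(self, tmp_path):
        batch = rq.generate_qc_batch(400.0, 6, 1.0, 106.0, 2.0, seed=4)
        path = tmp_path / "diss.csv"
        ids = [f"V{i}" for i in range(6)]
        io.write_dissolution(path, ids, batch.dissolution_times_min, batch.dissolution_pct)
        rids, times, profiles = io.read_dissolution(path)
        assert rids == ids
        np.testing.assert_array_equal(times, batch.dissolution_times_min)
        np.testing.assert_array_equal(profiles, batch.dissolution_pct)


class TestModelArtifact:
    def test_saved_model_predicts_identically(self, tmp_path, fitted_default):
        study, train, test, results = fitted_default
        path = tmp_path / "model.json"
        results.save(path)
        predictor = RamanContentResults.load_predictor(path)
        np.testing.assert_allclose(
            predictor.predict(study.spectra[test]),
            results.predict(study.spectra[test]),
            atol=1e-12,
        )

    def test_summary_mentions_key_quantities(self, fitted_default):
        *_, results = fitted_default
        text = results.summary()
        assert "latent variables" in text
        assert "RMSECV" in text
        assert "VIP" in text


class TestCLI:
    def test_qc_content_command(self, tmp_path):
        table = tmp_path / "contents.csv"
        pd.DataFrame({"content_pct": np.full(10, 104.0)}).to_csv(table, index=False)
        runner = CliRunner()
        res = runner.invoke(cli_main, ["qc", "content", "--table", str(table)])
        assert res.exit_code == 0
        assert "AV" in res.output and "PASS" in res.output

    def test_qc_mass_command(self, tmp_path):
        table = tmp_path / "masses.csv"
        pd.DataFrame({"tablet_id": ["a", "b"], "mass_mg": [400.0, 422.0]}).to_csv(
            table, index=False
        )
        runner = CliRunner()
        res = runner.invoke(cli_main, ["qc", "mass", "--table", str(table),
                                       "--nominal-mg", "400"])
        assert res.exit_code == 0
        assert "50.0%" in res.output

    def test_validation_error_exit_code(self, tmp_path):
        table = tmp_path / "contents.csv"
        pd.DataFrame({"content_pct": np.full(7, 104.0)}).to_csv(table, index=False)
        runner = CliRunner()
        res = runner.invoke(cli_main, ["qc", "content", "--table", str(table)])
        assert res.exit_code == 2

    def test_simulate_then_train_then_predict(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data"
        res = runner.invoke(cli_main, ["simulate", "--seed", "5", "--out", str(data)])
        assert res.exit_code == 0, res.output
        model = tmp_path / "model.json"
        res = runner.invoke(cli_main, [
            "train", "--spectra", str(data / "spectra.csv"),
            "--metadata", str(data / "metadata.csv"), "--model-out", str(model),
        ])
        assert res.exit_code == 0, res.output
        preds = tmp_path / "pred.csv"
        res = runner.invoke(cli_main, [
            "predict", "--model", str(model),
            "--spectra", str(data / "spectra.csv"), "--out", str(preds),
        ])
        assert res.exit_code == 0, res.output
        df = pd.read_csv(preds)
        assert df.shape[0] == 65
        assert np.all(np.isfinite(df["predicted_content_mg"]))
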