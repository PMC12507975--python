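"""Shared fixtures.

The expensive multi-seed study sweep is computed once per session and
reused by the property and acceptance tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import ramanqc as rq

N_SWEEP_SEEDS = 20


@pytest.fixture(scope="session")
def default_study():
    """One default 65-tablet synthetic calibration study."""
    return rq.generate_calibration_study(rq.SyntheticBatchConfig(seed=0))


@pytest.fixture(scope="session")
def fitted_default():
    """Fitted calibration on the training half of the default study."""
    study = rq.generate_calibration_study(rq.SyntheticBatchConfig(seed=0))
    train, test = rq.split_train_test(study.dose_mg, rng=np.random.default_rng(1000))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = rq.RamanContentModel.from_study(study, indices=train).fit()
    return study, train, test, results


@pytest.fixture(scope="session")
def seed_sweep():
    """Twenty fitted default studies (seeds 0..19): recovery and CV statistics."""
    out = []
    for seed in range(N_SWEEP_SEEDS):
        study = rq.generate_calibration_study(rq.SyntheticBatchConfig(seed=seed))
        train, test = rq.split_train_test(study.dose_mg, rng=np.random.default_rng(1000 + seed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = rq.RamanContentModel.from_study(study, indices=train).fit()
        y_true = study.true_content_mg[test]
        y_hat = results.predict(study.spectra[test])
        report = results.evaluate(study.spectra[test], study.reference_content_mg[test])
        out.append(
            {
                "seed": seed,
                "n_lv": results.n_lv,
                "slope_true": float(np.polyfit(y_true, y_hat, 1)[0]),
                "r2_true": rq.pls.regression_metrics(y_true, y_hat)[0],
                "report": report,
            }
        )
    return out
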