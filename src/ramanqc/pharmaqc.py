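"""Pharmacopoeial batch computations for extruded tablets.

Three checks, as applied to personalised semi-solid extruded tablets:

* **Mass uniformity / dosing accuracy** — each tablet's mass may deviate
  from nominal by at most 5% for tablets over 250 mg and 7.5% for tablets
  of 250 mg or less (Ph. Eur. 2.9.5-style limits); dosing accuracy is the
  percentage of tablets within the limit.
* **Content uniformity** — the first-stage Acceptance Value of Ph. Eur.
  2.9.40 for n = 10 tablets at target T = 100% of label:
  ``AV = |M - mean| + k*s`` with k = 2.4, sample standard deviation s and
  reference value M clipped to the [98.5, 101.5] band.  The batch passes
  when AV < 15.
* **Dissolution** — immediate-release compliance: at least 80% of the
  label claim released at the 30-minute checkpoint for every tablet
  tested (USP ondansetron tablet Test 2 criterion).

Values are percentages of nominal/label throughout; standard deviations are
the sample (n-1) form, matching pharmacopoeial practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MassUniformityResult",
    "ContentUniformityResult",
    "DissolutionResult",
    "mass_uniformity",
    "rsd_pct",
    "acceptance_value",
    "av_from_summary",
    "dissolution_compliance",
]

#: Mass-deviation limits (% of nominal) either side of the 250 mg cutoff.
MASS_LIMIT_LARGE_PCT = 5.0  # nominal > 250 mg
MASS_LIMIT_SMALL_PCT = 7.5  # nominal <= 250 mg
MASS_CUTOFF_MG = 250.0

#: First-stage content-uniformity constants (n = 10, T = 100% of label).
CU_N = 10
CU_K = 2.4
CU_M_LOW = 98.5
CU_M_HIGH = 101.5
CU_AV_LIMIT = 15.0


@dataclass
class MassUniformityResult:
    deviation_pct: np.ndarray
    passed: np.ndarray
    dosing_accuracy_pct: float
    threshold_used_pct: float
    nominal_mass_mg: float


@dataclass
class ContentUniformityResult:
    n: int
    mean_pct: float
    s_pct: float
    k: float
    m_reference: float
    av: float
    av_rounded: int
    passed: bool


@dataclass
class DissolutionResult:
    released_at_checkpoint_pct: np.ndarray
    tablet_passed: np.ndarray
    batch_passed: bool
    checkpoint_min: float
    threshold_pct: float


def mass_uniformity(masses_mg: np.ndarray, nominal_mg: float) -> MassUniformityResult:
    """Flag tablets outside the pharmacopoeial mass-deviation limit.

    Deviation is ``100 (m - nominal) / nominal``; the limit is 5% above the
    250 mg cutoff and 7.5% at or below it (the boundary itself takes the
    lenient small-tablet limit, a convention fixed for determinism).
    Dosing accuracy is the percentage of passing tablets.
    """
    masses = np.asarray(masses_mg, dtype=float).ravel()
    if masses.size < 1:
        raise ValueError("need at least one tablet mass")
    if nominal_mg <= 0:
        raise ValueError("nominal mass must be positive")
    if np.any(masses <= 0):
        raise ValueError("tablet masses must be positive")
    limit = MASS_LIMIT_LARGE_PCT if nominal_mg > MASS_CUTOFF_MG else MASS_LIMIT_SMALL_PCT
    dev = 100.0 * (masses - nominal_mg) / nominal_mg
    ok = np.abs(dev) <= limit + 1e-12
    return MassUniformityResult(
        deviation_pct=dev,
        passed=ok,
        dosing_accuracy_pct=100.0 * float(np.count_nonzero(ok)) / masses.size,
        threshold_used_pct=limit,
        nominal_mass_mg=float(nominal_mg),
    )


def rsd_pct(values: np.ndarray) -> float:
    """Relative standard deviation: 100 x sample SD / mean."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("RSD needs at least two values")
    mean = float(v.mean())
    if mean == 0.0:
        raise ValueError("RSD undefined for zero mean")
    return 100.0 * float(v.std(ddof=1)) / mean


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _av_core(mean_pct: float, s_pct: float, n: int) -> ContentUniformityResult:
    if n != CU_N:
        raise ValueError(
            f"only the first-stage test (n = {CU_N}) is supported; got n = {n}"
        )
    if mean_pct < CU_M_LOW:
        m_ref = CU_M_LOW
    elif mean_pct > CU_M_HIGH:
        m_ref = CU_M_HIGH
    else:
        m_ref = mean_pct
    av = abs(m_ref - mean_pct) + CU_K * s_pct
    return ContentUniformityResult(
        n=n,
        mean_pct=float(mean_pct),
        s_pct=float(s_pct),
        k=CU_K,
        m_reference=float(m_ref),
        av=float(av),
        av_rounded=_round_half_away(av),
        passed=bool(av < CU_AV_LIMIT),
    )


def acceptance_value(contents_pct: np.ndarray, n: int = CU_N) -> ContentUniformityResult:
    """First-stage content-uniformity Acceptance Value from per-tablet assays.

    ``contents_pct`` are individual contents as % of the label claim; exactly
    10 tablets are required (the first pharmacopoeial stage).  The batch
    passes when AV < 15.  The exact AV is reported together with its
    half-away-from-zero integer rounding, the form batch certificates print.
    """
    c = np.asarray(contents_pct, dtype=float).ravel()
    if c.size != CU_N or n != CU_N:
        raise ValueError(f"first-stage content uniformity requires exactly {CU_N} tablets")
    return _av_core(float(c.mean()), float(c.std(ddof=1)), CU_N)


def av_from_summary(mean_pct: float, rsd_pct: float, n: int = CU_N) -> ContentUniformityResult:
    """Acceptance Value reconstructed from a reported mean and %RSD.

    Converts the summary back to a standard deviation
    (``s = rsd * mean / 100``) and applies the same first-stage AV rules —
    useful for checking batch records that report only summary
    statistics.
    """
    if rsd_pct < 0:
        raise ValueError("RSD must be non-negative")
    s = rsd_pct * mean_pct / 100.0
    return _av_core(float(mean_pct), float(s), n)


def dissolution_compliance(
    times_min: np.ndarray,
    released_pct: np.ndarray,
    checkpoint_min: float = 30.0,
    threshold_pct: float = 80.0,
) -> DissolutionResult:
    """Immediate-release compliance at a fixed checkpoint (default 30 min, 80%).

    ``released_pct`` is (n_tablets, n_times); the checkpoint must be one of
    the sampled times (no interpolation).  Every tablet must reach the
    threshold for the batch to pass.
    """
    times = np.asarray(times_min, dtype=float).ravel()
    profiles = np.atleast_2d(np.asarray(released_pct, dtype=float))
    if profiles.shape[1] != times.size:
        raise ValueError("profile columns must match the time axis")
    hit = np.flatnonzero(np.isclose(times, checkpoint_min))
    if hit.size == 0:
        raise ValueError(f"checkpoint {checkpoint_min} min not in the sampling times {times}")
    at = profiles[:, hit[0]]
    ok = at >= threshold_pct
    return DissolutionResult(
        released_at_checkpoint_pct=at,
        tablet_passed=ok,
        batch_passed=bool(np.all(ok)),
        checkpoint_min=float(checkpoint_min),
        threshold_pct=float(threshold_pct),
    )
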