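"""Synthetic Raman spectra and batch records for semi-solid extruded tablets.

This module emulates the measurement campaign behind a Raman-based
content-calibration study of ondansetron tablets produced by semi-solid
extrusion: five dose levels (2, 4, 6, 8 and 10 mg of API in a 400 mg
tablet), thirteen tablets per level, five Raman replicates per tablet that
are later averaged to one spectrum per tablet, plus the batch records
(tablet masses, assayed contents, dissolution time series) that the
pharmacopoeial checks consume.

Each simulated spectrum is a linear mixture of three independent spectral
sources — the API signature and two excipient factors (a gel/protein base
and a lipid fraction) — on top of a smooth random baseline drift and
additive i.i.d. noise.  The API signature carries the seven prominent
ondansetron bands (529, 670, 1022, 1206, 1349, 1527 and 1619 cm⁻¹); the
excipient factors carry the glycerol/gel band near 1059 cm⁻¹, the amide-III
region near 1265 cm⁻¹, the C–H / lipid region near 1455 cm⁻¹ and the
amide-I region near 1650 cm⁻¹.  The top dose level receives extra
replicate-to-replicate amplitude jitter, emulating the elevated measurement
variability observed for the strongest tablets.

All randomness flows from a single :class:`numpy.random.Generator`, so an
identical configuration and seed reproduce a batch bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PeakSpec",
    "ComponentSignature",
    "SyntheticBatchConfig",
    "CalibrationStudy",
    "QCBatch",
    "API_PEAK_CENTERS",
    "DISSOLUTION_SAMPLING_TIMES_MIN",
    "ondansetron_signature",
    "gel_base_signature",
    "lipid_signature",
    "render_component",
    "generate_tablet_measurement",
    "generate_calibration_study",
    "generate_qc_batch",
]

#: Prominent ondansetron Raman bands (cm^-1).
API_PEAK_CENTERS = (529.0, 670.0, 1022.0, 1206.0, 1349.0, 1527.0, 1619.0)

#: Dissolution sampling grid (minutes after immersion).
DISSOLUTION_SAMPLING_TIMES_MIN = (5.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0)

_GAUSS_K = 4.0 * np.log(2.0)  # FWHM parametrisation constant


@dataclass(frozen=True)
class PeakSpec:
    """One spectral band: unit-apex profile scaled by ``amplitude`` per unit concentration.

    Parameters
    ----------
    center : float
        Band position in cm^-1.
    fwhm : float
        Full width at half maximum in cm^-1; must be positive.
    amplitude : float
        Apex intensity contributed per unit concentration (counts per mg for
        the defaults used here); must be non-negative.
    shape : {"gaussian", "lorentzian"}
        Line-shape family.
    """

    center: float
    fwhm: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"fwhm must be positive, got {self.fwhm}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be non-negative, got {self.amplitude}")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown peak shape {self.shape!r}")

    def profile(self, grid: np.ndarray) -> np.ndarray:
        """Unit-apex line shape evaluated on ``grid``."""
        x = np.asarray(grid, dtype=float)
        d = x - self.center
        if self.shape == "gaussian":
            return np.exp(-_GAUSS_K * (d / self.fwhm) ** 2)
        # lorentzian
        hw = self.fwhm / 2.0
        return hw**2 / (d**2 + hw**2)


@dataclass(frozen=True)
class ComponentSignature:
    """A named spectral component: an ordered collection of peaks.

    Rendering is linear in concentration; signatures are validated against a
    wavenumber grid once, at configuration time, so rendering itself never
    rejects a peak.
    """

    name: str
    peaks: tuple[PeakSpec, ...]

    def __post_init__(self) -> None:
        if len(self.peaks) == 0:
            raise ValueError(f"signature {self.name!r} must have at least one peak")

    def validate_grid(self, grid: np.ndarray) -> None:
        """Raise if any peak centre falls outside ``[grid[0], grid[-1]]``."""
        grid = np.asarray(grid, dtype=float)
        lo, hi = grid[0], grid[-1]
        for pk in self.peaks:
            if not (lo <= pk.center <= hi):
                raise ValueError(
                    f"peak at {pk.center} cm-1 of component {self.name!r} "
                    f"lies outside the grid [{lo}, {hi}]"
                )

    def render(self, grid: np.ndarray, concentration: float) -> np.ndarray:
        return render_component(self, grid, concentration)


def render_component(
    signature: ComponentSignature, grid: np.ndarray, concentration: float
) -> np.ndarray:
    """Render one component at a given concentration.

    Returns ``sum_k amplitude_k * shape_k(grid) * concentration`` — exactly
    linear in ``concentration`` and additive over peaks.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a strictly increasing 1-D axis")
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    out = np.zeros_like(grid)
    for pk in signature.peaks:
        out += pk.amplitude * concentration * pk.profile(grid)
    return out


def ondansetron_signature(amplitude_per_mg: float = 6.0) -> ComponentSignature:
    """API signature with the seven characteristic ondansetron bands.

    ``amplitude_per_mg`` scales the strongest band (1022 cm^-1); the other
    bands keep fixed relative heights.
    """
    rel = (0.70, 0.60, 1.00, 0.50, 0.85, 0.55, 0.90)
    fwhm = (10.0, 12.0, 9.0, 11.0, 13.0, 11.0, 12.0)
    peaks = tuple(
        PeakSpec(center=c, fwhm=w, amplitude=amplitude_per_mg * r)
        for c, w, r in zip(API_PEAK_CENTERS, fwhm, rel)
    )
    return ComponentSignature("ondansetron", peaks)


def gel_base_signature(amplitude_per_mg: float = 0.8) -> ComponentSignature:
    """Gel/protein excipient factor: glycerol 1059, amide-III 1265, amide-I 1650 cm^-1.

    Amplitudes are per mg of gel mass; with ~330 mg of gel in a 400 mg tablet
    the excipient bands dominate the API bands at the 2 mg dose.
    """
    peaks = (
        PeakSpec(center=1059.0, fwhm=32.0, amplitude=amplitude_per_mg),
        PeakSpec(center=1265.0, fwhm=55.0, amplitude=0.55 * amplitude_per_mg),
        PeakSpec(center=1650.0, fwhm=48.0, amplitude=0.85 * amplitude_per_mg),
    )
    return ComponentSignature("gel_base", peaks)


def lipid_signature(amplitude_per_mg: float = 4.0) -> ComponentSignature:
    """Lipid (cocoa-butter) excipient factor.

    CH2 twist near 1302, CH2 deformation doublet at 1445/1468 and the C=C
    stretch near 1657 cm^-1 — the latter two genuinely overlapping the API
    bands at 1349 and 1619 cm^-1, as lipid and amide regions do in gelatin/
    cocoa-butter matrices.
    """
    peaks = (
        PeakSpec(center=1302.0, fwhm=46.0, amplitude=0.5 * amplitude_per_mg),
        PeakSpec(center=1445.0, fwhm=38.0, amplitude=amplitude_per_mg),
        PeakSpec(center=1468.0, fwhm=30.0, amplitude=0.6 * amplitude_per_mg),
        PeakSpec(center=1657.0, fwhm=40.0, amplitude=0.7 * amplitude_per_mg),
    )
    return ComponentSignature("lipid", peaks)


@dataclass
class SyntheticBatchConfig:
    """Study design and noise model for one synthetic calibration campaign.

    Defaults reproduce the 65-tablet design: 5 dose levels x 13 tablets,
    5 replicates each, 400 mg tablets on a 400-1800 cm^-1 grid with 2 cm^-1
    spacing.

    Attributes
    ----------
    dose_levels_mg : sequence of float
        API amount per tablet at each calibration level.
    tablets_per_level, replicates_per_tablet : int
        Design counts; replicates are averaged downstream to one spectrum
        per tablet.
    tablet_mass_mg : float
        Nominal tablet mass; excipient mass is ``tablet_mass - API mass``.
    grid_min, grid_max, grid_step : float
        Wavenumber grid (cm^-1).
    noise_sd : float
        SD of additive i.i.d. noise per replicate point (counts).
    baseline_amplitude : float
        Scale of the random degree-3 polynomial drift added per replicate
        (small by default: a time-gated spectrometer suppresses most
        fluorescence background).
    api_sampling_rsd_pct : float
        Tablet-level relative SD of the API signal amplitude, emulating
        sub-sampling error: the probe interrogates a small rotated area
        whose local drug loading differs from the tablet mean.  This is the
        dominant irreducible error of the calibration.
    high_dose_extra_cv : float
        Extra relative amplitude jitter applied per replicate at the top
        dose level only (elevated variability of the strongest tablets).
    content_bias_pct, content_rsd_pct : float
        Mean and relative SD of the realised tablet content as % of label
        (manufacturing spread).
    assay_rsd_pct : float
        Relative SD of the recorded reference content around the true
        simulated content.  This emulates the *effective* discrepancy
        between the destructive reference assay and what the probe sees —
        chromatographic precision plus extraction/volumetric losses — and
        sets the irreducible validation error of the calibration.
    excipient_rsd_pct : float
        Tablet-to-tablet relative SD of each excipient factor's intensity
        scale (mixing inhomogeneity); the two factors jitter independently.
    gel_mass_fraction : float
        Share of the excipient mass assigned to the gel factor.
    seed : int
        Seed for the single random generator all draws flow from.
    """

    dose_levels_mg: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0, 10.0)
    tablets_per_level: int = 13
    replicates_per_tablet: int = 5
    tablet_mass_mg: float = 400.0
    grid_min: float = 400.0
    grid_max: float = 1800.0
    grid_step: float = 2.0
    noise_sd: float = 2.0
    baseline_amplitude: float = 15.0
    api_sampling_rsd_pct: float = 3.0
    high_dose_extra_cv: float = 0.04
    content_bias_pct: float = 106.0
    content_rsd_pct: float = 2.0
    assay_rsd_pct: float = 8.0
    excipient_rsd_pct: float = 20.0
    gel_mass_fraction: float = 0.85
    seed: int = 0
    api_signature: ComponentSignature = field(default_factory=ondansetron_signature)
    excipient_signatures: tuple[ComponentSignature, ...] = field(
        default_factory=lambda: (gel_base_signature(), lipid_signature())
    )

    def __post_init__(self) -> None:
        self.dose_levels_mg = tuple(float(d) for d in self.dose_levels_mg)
        if len(self.dose_levels_mg) < 1 or any(d <= 0 for d in self.dose_levels_mg):
            raise ValueError("dose_levels_mg must be non-empty and positive")
        for name in ("tablets_per_level", "replicates_per_tablet"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.tablet_mass_mg <= max(self.dose_levels_mg):
            raise ValueError("tablet_mass_mg must exceed the largest dose")
        if self.grid_step <= 0 or self.grid_max <= self.grid_min:
            raise ValueError("grid must be strictly increasing")
        if self.noise_sd < 0 or self.baseline_amplitude < 0:
            raise ValueError("noise_sd and baseline_amplitude must be >= 0")
        if min(self.high_dose_extra_cv, self.excipient_rsd_pct, self.api_sampling_rsd_pct) < 0:
            raise ValueError("variability parameters must be >= 0")
        if not (0.0 < self.gel_mass_fraction < 1.0):
            raise ValueError("gel_mass_fraction must lie in (0, 1)")
        grid = self.grid
        self.api_signature.validate_grid(grid)
        for sig in self.excipient_signatures:
            sig.validate_grid(grid)

    @property
    def grid(self) -> np.ndarray:
        """Strictly increasing wavenumber axis (cm^-1)."""
        return np.arange(self.grid_min, self.grid_max + self.grid_step / 2.0, self.grid_step)

    @property
    def n_tablets(self) -> int:
        return len(self.dose_levels_mg) * self.tablets_per_level

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # signatures are structural, not free parameters; store names only
        d["api_signature"] = self.api_signature.name
        d["excipient_signatures"] = [s.name for s in self.excipient_signatures]
        return d


@dataclass
class CalibrationStudy:
    """Output of one simulated calibration campaign.

    ``spectra`` holds the replicate-averaged spectrum per tablet (rows in
    acquisition order: dose levels ascending, tablets sequential within a
    level); ``raw`` keeps the individual replicates.  Both the true realised
    content and the assayed (HPLC-like) reference content are recorded so
    parameter-recovery checks can use either.
    """

    config: SyntheticBatchConfig
    wavenumbers: np.ndarray
    spectra: np.ndarray  # (n_tablets, n_points) replicate averages
    raw: np.ndarray  # (n_tablets, n_replicates, n_points)
    dose_mg: np.ndarray
    true_content_mg: np.ndarray
    reference_content_mg: np.ndarray
    sample_ids: list[str]

    @property
    def reference_content_pct(self) -> np.ndarray:
        """Assayed content as % of the label claim."""
        return 100.0 * self.reference_content_mg / self.dose_mg


@dataclass
class QCBatch:
    """Batch record for pharmacopoeial checks.

    ``dissolution_pct`` is (n_tablets, n_times) with per-tablet % of label
    released at ``dissolution_times_min``; profiles are non-decreasing in
    time and bounded by ``release_ceiling_pct``.
    """

    tablet_masses_mg: np.ndarray
    nominal_mass_mg: float
    assayed_content_pct: np.ndarray
    dissolution_times_min: np.ndarray
    dissolution_pct: np.ndarray
    release_ceiling_pct: float = 100.0

    def __post_init__(self) -> None:
        self.tablet_masses_mg = np.asarray(self.tablet_masses_mg, dtype=float)
        self.assayed_content_pct = np.asarray(self.assayed_content_pct, dtype=float)
        self.dissolution_times_min = np.asarray(self.dissolution_times_min, dtype=float)
        self.dissolution_pct = np.atleast_2d(np.asarray(self.dissolution_pct, dtype=float))
        if np.any(self.tablet_masses_mg <= 0):
            raise ValueError("tablet masses must be positive")
        if self.release_ceiling_pct < 100.0:
            raise ValueError("release ceiling must be >= 100%")
        if np.any(np.diff(self.dissolution_pct, axis=1) < -1e-9):
            raise ValueError("dissolution profiles must be non-decreasing in time")
        if np.any(self.dissolution_pct > self.release_ceiling_pct + 1e-9):
            raise ValueError("dissolution exceeds the release ceiling")


# ---------------------------------------------------------------------------
# generation


def _random_baseline(grid: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth degree-3 polynomial drift with random coefficients."""
    # always draw, so the stream is identical whether or not drift is enabled
    coeffs = rng.normal(size=4)
    if amplitude == 0.0:
        return np.zeros_like(grid)
    u = np.linspace(-1.0, 1.0, grid.size)
    damp = np.array([1.0, 0.6, 0.4, 0.25])
    return amplitude * np.polynomial.polynomial.polyval(u, coeffs * damp)


def _tablet_state(
    config: SyntheticBatchConfig, dose_mg: float, rng: np.random.Generator
) -> tuple[float, np.ndarray, float]:
    """Draw one tablet's realised content, excipient scales and API sampling factor."""
    content = dose_mg * (config.content_bias_pct / 100.0) * (
        1.0 + rng.normal() * config.content_rsd_pct / 100.0
    )
    content = max(content, 0.0)
    scales = 1.0 + rng.normal(size=len(config.excipient_signatures)) * (
        config.excipient_rsd_pct / 100.0
    )
    api_scale = max(1.0 + rng.normal() * config.api_sampling_rsd_pct / 100.0, 0.0)
    return content, np.clip(scales, 0.0, None), api_scale


def _replicate_spectrum(
    config: SyntheticBatchConfig,
    dose_mg: float,
    content_mg: float,
    excip_scales: np.ndarray,
    api_scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    grid = config.grid
    excipient_mass = config.tablet_mass_mg - content_mg
    masses = np.array(
        [config.gel_mass_fraction * excipient_mass, (1.0 - config.gel_mass_fraction) * excipient_mass]
    )
    api_jitter = api_scale
    if dose_mg == max(config.dose_levels_mg) and config.high_dose_extra_cv > 0:
        api_jitter *= 1.0 + rng.normal() * config.high_dose_extra_cv
    y = render_component(config.api_signature, grid, content_mg) * api_jitter
    for sig, m, s in zip(config.excipient_signatures, masses, excip_scales):
        y += render_component(sig, grid, m) * s
    y += _random_baseline(grid, config.baseline_amplitude, rng)
    noise = rng.normal(size=grid.size)
    if config.noise_sd > 0:
        y += config.noise_sd * noise
    return y


def generate_tablet_measurement(
    config: SyntheticBatchConfig,
    dose_mg: float,
    rng: np.random.Generator,
    content_mg: float | None = None,
) -> np.ndarray:
    """Simulate one Raman replicate of one tablet.

    If ``content_mg`` is None, the tablet's realised content and excipient
    scales are drawn first (as for a fresh tablet).
    """
    if not (min(config.dose_levels_mg) <= dose_mg <= max(config.dose_levels_mg)):
        raise ValueError(f"dose {dose_mg} mg outside configured range")
    if content_mg is None:
        content_mg, scales, api_scale = _tablet_state(config, dose_mg, rng)
    else:
        scales = np.ones(len(config.excipient_signatures))
        api_scale = 1.0
    return _replicate_spectrum(config, dose_mg, content_mg, scales, api_scale, rng)


def generate_calibration_study(
    config: SyntheticBatchConfig, rng: np.random.Generator | None = None
) -> CalibrationStudy:
    """Simulate the full calibration campaign defined by ``config``.

    Tablets are generated in acquisition order: the session cycles through
    the dose levels round-robin (tablet 1 of every level, then tablet 2,
    ...), so consecutive measurement blocks are dose-balanced.  Each tablet
    gets ``replicates_per_tablet`` raw spectra plus their pointwise
    average, a realised (true) content and an assayed reference content.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    grid = config.grid
    n = config.n_tablets
    r = config.replicates_per_tablet
    raw = np.empty((n, r, grid.size))
    dose = np.empty(n)
    true_content = np.empty(n)
    ref_content = np.empty(n)
    ids: list[str] = []
    i = 0
    for t in range(config.tablets_per_level):
        for d in config.dose_levels_mg:
            content, scales, api_scale = _tablet_state(config, d, rng)
            for k in range(r):
                raw[i, k] = _replicate_spectrum(config, d, content, scales, api_scale, rng)
            dose[i] = d
            true_content[i] = content
            ref_content[i] = content * (1.0 + rng.normal() * config.assay_rsd_pct / 100.0)
            ids.append(f"D{d:04.1f}_T{t + 1:02d}")
            i += 1
    return CalibrationStudy(
        config=config,
        wavenumbers=grid,
        spectra=raw.mean(axis=1),
        raw=raw,
        dose_mg=dose,
        true_content_mg=true_content,
        reference_content_mg=ref_content,
        sample_ids=ids,
    )


def generate_qc_batch(
    nominal_mass_mg: float,
    n_tablets: int,
    mass_rsd_pct: float,
    content_mean_pct: float,
    content_rsd_pct: float,
    dissolution_rate_per_min: float = 0.1,
    dissolution_rate_rsd_pct: float = 10.0,
    release_ceiling_pct: float = 100.0,
    sampling_times_min: Sequence[float] = DISSOLUTION_SAMPLING_TIMES_MIN,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> QCBatch:
    """Simulate a QC batch: masses, assayed contents and dissolution profiles.

    Masses are ``nominal x (1 + e)`` with relative error SD ``mass_rsd_pct``;
    contents are normal with the stated mean and RSD (% of label);
    dissolution follows a saturating first-order release
    ``ceiling * (1 - exp(-k t))`` with per-tablet rate jitter.
    """
    if n_tablets < 1:
        raise ValueError("n_tablets must be >= 1")
    if nominal_mass_mg <= 0:
        raise ValueError("nominal mass must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    masses = nominal_mass_mg * (1.0 + rng.normal(size=n_tablets) * mass_rsd_pct / 100.0)
    contents = content_mean_pct * (1.0 + rng.normal(size=n_tablets) * content_rsd_pct / 100.0)
    times = np.asarray(sampling_times_min, dtype=float)
    rates = dissolution_rate_per_min * (
        1.0 + rng.normal(size=n_tablets) * dissolution_rate_rsd_pct / 100.0
    )
    rates = np.clip(rates, 1e-6, None)
    profiles = release_ceiling_pct * (1.0 - np.exp(-np.outer(rates, times)))
    return QCBatch(
        tablet_masses_mg=masses,
        nominal_mass_mg=float(nominal_mass_mg),
        assayed_content_pct=contents,
        dissolution_times_min=times,
        dissolution_pct=profiles,
        release_ceiling_pct=float(release_ceiling_pct),
    )
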