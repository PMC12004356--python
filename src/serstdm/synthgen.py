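"""Synthetic SERS data generator for the meropenem serum assay.

Emulates the statistical structure of drug-on-chip SERS measurements so that
every downstream stage (map reduction, PLSR calibration, validation,
method-agreement analysis) is testable without instrument data:

* meropenem bands at 1559 (dominant), 1387, 1052, 890, 771, 709 and 670
  cm^-1 whose amplitude grows linearly with concentration;
* serum interferent bands (notably uric acid at 640 cm^-1) whose level
  depends on the serum cleanup method (protein precipitation worst,
  mono-spin solid-phase extraction best);
* a smooth polynomial substrate baseline, additive homoscedastic Gaussian
  channel noise, and log-normal pixel-to-pixel enhancement heterogeneity
  across a chip map.

All randomness flows through a single integer seed per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import CalibrationDataset, PairedCohort, SpectralMap, Spectrum

__all__ = [
    "BandSpec",
    "CleanupEffect",
    "GeneratorConfig",
    "default_analyte_bands",
    "default_interferent_bands",
    "generate_spectrum",
    "generate_map",
    "generate_calibration_dataset",
    "generate_paired_cohort",
    "DEFAULT_LEVELS_UM",
    "THERAPEUTIC_RANGE_UM",
]

#: Default calibration levels (uM); six levels x five replicates give the
#: 30-row calibration matrix the models expect.
DEFAULT_LEVELS_UM: Tuple[float, ...] = (25.0, 50.0, 100.0, 250.0, 500.0, 750.0)

#: Meropenem serum concentrations seen in ICU patients span roughly this range.
THERAPEUTIC_RANGE_UM: Tuple[float, float] = (20.0, 450.0)


@dataclass(frozen=True)
class BandSpec:
    """One vibrational band.

    ``response`` is amplitude per uM for analyte bands, or a fixed amplitude
    (intensity units) for interferent bands.  ``width`` is the full width at
    half maximum in cm^-1.
    """

    center: float
    width: float
    response: float
    shape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width (FWHM) must be positive")
        if self.response < 0:
            raise ValueError("band response must be non-negative")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown line shape {self.shape!r}")

    def profile(self, axis: np.ndarray) -> np.ndarray:
        """Unit-peak line profile on ``axis``."""
        d = np.asarray(axis, dtype=float) - self.center
        if self.shape == "lorentzian":
            hwhm = self.width / 2.0
            return hwhm**2 / (d**2 + hwhm**2)
        # gaussian parameterized by FWHM
        return np.exp(-4.0 * math.log(2.0) * d**2 / self.width**2)


@dataclass(frozen=True)
class CleanupEffect:
    """Spectral consequences of one serum cleanup method.

    ``interferent_scale`` multiplies serum interferent band amplitudes,
    ``noise_scale`` multiplies the additive channel noise (residual matrix
    raises the noise floor), and ``analyte_recovery`` multiplies the analyte
    response (matrix molecules competing for the metal surface suppress
    analyte adsorption).  Together these reproduce the observed ordering
    ms-SPE > UF (10k > 3k) > PP in both interferent suppression and SNR.
    """

    interferent_scale: float
    noise_scale: float
    analyte_recovery: float


DEFAULT_CLEANUP_EFFECTS: Dict[str, CleanupEffect] = {
    "PP": CleanupEffect(1.00, 2.00, 0.60),
    "UF3k": CleanupEffect(0.80, 1.80, 0.70),
    "UF10k": CleanupEffect(0.45, 1.40, 0.85),
    "msSPE": CleanupEffect(0.10, 1.00, 1.00),
}


def default_analyte_bands() -> List[BandSpec]:
    """Meropenem band set; 1559 cm^-1 (beta-lactam C=C stretch) dominates."""
    return [
        BandSpec(1559.0, 18.0, 1.00),
        BandSpec(1387.0, 16.0, 0.55),
        BandSpec(1052.0, 14.0, 0.30),
        BandSpec(890.0, 14.0, 0.35),
        BandSpec(771.0, 12.0, 0.22),
        BandSpec(709.0, 12.0, 0.18),
        BandSpec(670.0, 12.0, 0.15),
    ]


def default_interferent_bands() -> List[BandSpec]:
    """Residual serum bands; uric acid at 640 cm^-1 is the marker band."""
    return [
        BandSpec(640.0, 14.0, 180.0),
        BandSpec(1450.0, 40.0, 60.0),
    ]


def _default_axis() -> np.ndarray:
    # 696 channels spanning the 600-1800 cm^-1 fingerprint window used
    # throughout the analysis, so reduced calibration matrices are 30 x 696.
    return np.linspace(600.0, 1800.0, 696)


@dataclass
class GeneratorConfig:
    """All simulation assumptions in one place.

    Parameters
    ----------
    wavenumber_axis:
        Strictly increasing grid (cm^-1); default 696 channels over
        600-1800 cm^-1.
    analyte_bands, interferent_bands:
        Band sets; analyte responses are per uM.
    cleanup_method:
        One of ``PP``, ``UF3k``, ``UF10k``, ``msSPE`` (default), selecting a
        :class:`CleanupEffect`.
    baseline_coefficients:
        Polynomial coefficients c0, c1, c2, ... of the substrate background
        evaluated on the axis normalized to [0, 1].
    noise_sd:
        Additive Gaussian channel noise SD (intensity units) before the
        cleanup noise scale is applied.
    pixel_heterogeneity:
        Sigma of the log-normal per-pixel multiplicative enhancement factor;
        parameterized to have mean 1 so band height stays linear in
        concentration in expectation.
    """

    wavenumber_axis: np.ndarray = field(default_factory=_default_axis)
    analyte_bands: List[BandSpec] = field(default_factory=default_analyte_bands)
    interferent_bands: List[BandSpec] = field(default_factory=default_interferent_bands)
    cleanup_method: str = "msSPE"
    cleanup_effects: Dict[str, CleanupEffect] = field(
        default_factory=lambda: dict(DEFAULT_CLEANUP_EFFECTS)
    )
    baseline_coefficients: Tuple[float, ...] = (120.0, -60.0, 40.0)
    noise_sd: float = 4.0
    pixel_heterogeneity: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        self.wavenumber_axis = np.asarray(self.wavenumber_axis, dtype=float)
        if self.wavenumber_axis.ndim != 1 or self.wavenumber_axis.size < 2:
            raise ValueError("wavenumber_axis must be a 1-D grid with >= 2 channels")
        if not np.all(np.diff(self.wavenumber_axis) > 0):
            raise ValueError("wavenumber_axis must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.pixel_heterogeneity < 0:
            raise ValueError("pixel_heterogeneity must be non-negative")
        if self.cleanup_method not in self.cleanup_effects:
            raise ValueError(
                f"unknown cleanup method {self.cleanup_method!r}; "
                f"choose from {sorted(self.cleanup_effects)}"
            )

    @property
    def cleanup(self) -> CleanupEffect:
        return self.cleanup_effects[self.cleanup_method]

    def with_cleanup(self, method: str) -> "GeneratorConfig":
        return replace(self, cleanup_method=method)


# ---------------------------------------------------------------------------
# signature construction (deterministic parts of a spectrum)
# ---------------------------------------------------------------------------


def _signatures(config: GeneratorConfig) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(analyte per-uM signature, interferent signature, baseline) on the axis."""
    axis = config.wavenumber_axis
    cleanup = config.cleanup
    analyte = np.zeros_like(axis)
    for band in config.analyte_bands:
        analyte += band.response * band.profile(axis)
    analyte *= cleanup.analyte_recovery
    interferent = np.zeros_like(axis)
    for band in config.interferent_bands:
        interferent += band.response * band.profile(axis)
    interferent *= cleanup.interferent_scale
    u = (axis - axis[0]) / (axis[-1] - axis[0])
    baseline = np.polynomial.polynomial.polyval(u, config.baseline_coefficients)
    return analyte, interferent, baseline


def _spectrum_array(
    concentration: float,
    enhancement: float,
    signatures: Tuple[np.ndarray, np.ndarray, np.ndarray],
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    analyte, interferent, baseline = signatures
    clean = baseline + enhancement * (analyte * concentration + interferent)
    if noise_sd > 0:
        clean = clean + rng.normal(0.0, noise_sd, size=clean.size)
    return clean


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------


def generate_spectrum(
    concentration: float,
    config: GeneratorConfig,
    enhancement: float = 1.0,
    seed: Optional[int] = None,
) -> Spectrum:
    """Simulate one SERS spectrum at a given analyte concentration (uM).

    intensities = baseline
                + sum(analyte bands) * response * concentration * enhancement
                + sum(interferent bands) * enhancement
                + N(0, noise_sd * cleanup.noise_scale) per channel
    """
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    if enhancement <= 0:
        raise ValueError("enhancement must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sig = _signatures(config)
    noise_sd = config.noise_sd * config.cleanup.noise_scale
    values = _spectrum_array(concentration, enhancement, sig, noise_sd, rng)
    return Spectrum(config.wavenumber_axis.copy(), values)


def _grid_coordinates(n_pixels: int) -> np.ndarray:
    ncol = math.ceil(math.sqrt(n_pixels))
    rows = np.arange(n_pixels) // ncol
    cols = np.arange(n_pixels) % ncol
    return np.column_stack([rows, cols])


def generate_map(
    concentration: float,
    n_pixels: int,
    config: GeneratorConfig,
    seed: Optional[int] = None,
    map_id: str = "map0",
) -> SpectralMap:
    """Simulate a chip scan: ``n_pixels`` spectra with heterogeneous enhancement.

    Per-pixel enhancement factors are log-normal with mean 1 and log-scale
    sigma ``config.pixel_heterogeneity``, emulating the hotspot-driven
    intensity nonuniformity of SERS heat maps.
    """
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sigma = config.pixel_heterogeneity
    if sigma > 0:
        # mean-1 log-normal: E[exp(N(-s^2/2, s))] = 1
        enh = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_pixels)
    else:
        enh = np.ones(n_pixels)
    sig = _signatures(config)
    noise_sd = config.noise_sd * config.cleanup.noise_scale
    pixels = np.empty((n_pixels, config.wavenumber_axis.size))
    for i in range(n_pixels):
        pixels[i] = _spectrum_array(concentration, enh[i], sig, noise_sd, rng)
    return SpectralMap(
        axis=config.wavenumber_axis.copy(),
        intensities=pixels,
        coordinates=_grid_coordinates(n_pixels),
        map_id=map_id,
    )


def generate_calibration_dataset(
    levels: Sequence[float] = DEFAULT_LEVELS_UM,
    replicates_per_level: int = 5,
    n_pixels: int = 64,
    config: Optional[GeneratorConfig] = None,
    seed: int = 0,
    reduction=None,
) -> CalibrationDataset:
    """Simulate maps over a concentration series and reduce each to one row.

    Each (level, replicate) pair yields one chip map which is collapsed to a
    representative spectrum by top-fraction pixel averaging
    (:func:`serstdm.preprocess.map_reduce_top_fraction`).  The default design
    (6 levels x 5 replicates on the 696-channel axis) produces the 30 x 696
    calibration matrix used by the PCA and PLSR stages.
    """
    from . import preprocess  # deferred: reduction lives downstream

    levels = list(levels)
    if len(levels) == 0:
        raise ValueError("levels must be non-empty")
    if any(lv < 0 for lv in levels):
        raise ValueError("levels must be non-negative")
    if replicates_per_level < 1:
        raise ValueError("replicates_per_level must be >= 1")
    if config is None:
        config = GeneratorConfig()
    if reduction is None:
        reduction = preprocess.ReductionConfig(
            crop_range=(config.wavenumber_axis[0], config.wavenumber_axis[-1])
        )

    root = np.random.default_rng(seed)
    rows: List[np.ndarray] = []
    meta: List[dict] = []
    axis_out: Optional[np.ndarray] = None
    for li, level in enumerate(levels):
        for rep in range(replicates_per_level):
            map_seed = int(root.integers(0, 2**31 - 1))
            smap = generate_map(
                level, n_pixels, config, seed=map_seed, map_id=f"L{li}R{rep}"
            )
            red = preprocess.map_reduce_top_fraction(smap, reduction)
            rows.append(red.spectrum.intensities)
            axis_out = red.spectrum.axis
            meta.append(
                {
                    "sample_id": f"L{li}R{rep}",
                    "concentration_uM": level,
                    "replicate": rep,
                    "map_id": smap.map_id,
                    "cleanup": config.cleanup_method,
                    "peak_height": red.peak_height,
                }
            )
    X = np.vstack(rows)
    y = np.repeat(levels, replicates_per_level).astype(float)
    return CalibrationDataset(X=X, y=y, axis=axis_out, metadata=pd.DataFrame(meta))


def generate_paired_cohort(
    n_patients: int = 27,
    concentration_range: Tuple[float, float] = THERAPEUTIC_RANGE_UM,
    reference_error_sd: float = 5.0,
    test_error_sd: float = 30.8,
    test_bias: float = -14.55,
    seed: int = 0,
) -> PairedCohort:
    """Paired reference/test concentration series with known ground truth.

    True concentrations are uniform over the therapeutic range (default
    20-450 uM).  The reference method (HPLC-like) reads truth plus small
    noise; the test method reads truth plus ``test_bias`` plus its own noise.
    Defaults mirror an ICU cohort of 27 patients whose Bland-Altman limits
    of agreement imply a difference SD near 31 uM and a mean difference near
    -15 uM (test - reference).
    """
    if n_patients < 3:
        raise ValueError("n_patients must be >= 3 (agreement statistics undefined)")
    if reference_error_sd < 0 or test_error_sd < 0:
        raise ValueError("error SDs must be non-negative")
    lo, hi = concentration_range
    if not (0 <= lo < hi):
        raise ValueError("concentration_range must satisfy 0 <= low < high")
    rng = np.random.default_rng(seed)
    truth = rng.uniform(lo, hi, size=n_patients)
    reference = truth + rng.normal(0.0, reference_error_sd, size=n_patients)
    test = truth + test_bias + rng.normal(0.0, test_error_sd, size=n_patients)
    return PairedCohort(truth=truth, reference=reference, test=test)
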