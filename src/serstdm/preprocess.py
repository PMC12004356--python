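"""Spectral preprocessing: crop, baseline correction, map reduction, SNR, scaling.

Mirrors the on-instrument analysis chain: each map pixel is cropped to the
fingerprint window and background-corrected, the map is reduced to one
representative spectrum by averaging the brightest fraction of pixels at the
quantification band (~1559 cm^-1), and dataset-level scaling prepares the
matrix for multivariate calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Tuple

import numpy as np
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter

from .types import SpectralMap, Spectrum

__all__ = [
    "ReductionConfig",
    "MapReduction",
    "Scaler",
    "crop",
    "baseline_correct",
    "estimate_baseline",
    "peak_height",
    "map_reduce_top_fraction",
    "snr",
    "scale_dataset",
    "SCALING_METHODS",
]

#: Quantification band for meropenem (beta-lactam C=C stretch), cm^-1.
TARGET_BAND_CM1 = 1559.0


@dataclass
class ReductionConfig:
    """How one chip map collapses to a representative spectrum.

    ``fraction`` is the proportion of brightest pixels averaged (default
    0.20: the top 20% of pixels ranked by background-corrected intensity at
    the target band).  The peak is located as the maximum inside
    ``target_band +/- window_halfwidth``.
    """

    target_band: float = TARGET_BAND_CM1
    window_halfwidth: float = 10.0
    fraction: float = 0.20
    crop_range: Tuple[float, float] = (600.0, 1800.0)
    correct_baseline: bool = True
    baseline_smoothness: float = 1e4
    baseline_asymmetry: float = 0.02

    def __post_init__(self) -> None:
        if not (0 < self.fraction <= 1):
            raise ValueError("fraction must lie in (0, 1]")
        if self.window_halfwidth < 0:
            raise ValueError("window_halfwidth must be non-negative")
        lo, hi = self.crop_range
        if lo >= hi:
            raise ValueError("crop_range must be (low, high) with low < high")
        if not (lo <= self.target_band <= hi):
            raise ValueError("target band window must lie inside the crop range")


@dataclass
class MapReduction:
    """Result of top-fraction map reduction."""

    spectrum: Spectrum  # channelwise mean of the selected pixels
    peak_height: float  # mean peak height of the selected pixels
    selected: np.ndarray  # indices of the selected pixels
    pixel_heights: np.ndarray  # per-pixel peak heights used for ranking


# ---------------------------------------------------------------------------
# crop
# ---------------------------------------------------------------------------


def crop(spectrum: Spectrum, crop_range: Tuple[float, float]) -> Spectrum:
    """Keep only channels whose wavenumber lies inside the closed range."""
    lo, hi = crop_range
    if lo > hi:
        raise ValueError("crop range must be (low, high)")
    mask = (spectrum.axis >= lo) & (spectrum.axis <= hi)
    if not mask.any():
        raise ValueError(
            f"crop range [{lo}, {hi}] does not overlap the axis "
            f"[{spectrum.axis[0]}, {spectrum.axis[-1]}]"
        )
    return Spectrum(spectrum.axis[mask], spectrum.intensities[mask])


# ---------------------------------------------------------------------------
# baseline correction (asymmetric least squares)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _second_diff_penalty_diagonals(n: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Diagonals of D'D for the (n-2) x n second-difference matrix D."""
    d0 = np.full(n, 6.0)
    d0[0] = d0[-1] = 1.0
    d0[1] = d0[-2] = 5.0
    d1 = np.full(n - 1, -4.0)
    d1[0] = d1[-1] = -2.0
    d2 = np.full(n - 2, 1.0)
    return d0, d1, d2


def estimate_baseline(
    intensities: np.ndarray,
    smoothness: float = 1e4,
    asymmetry: float = 0.02,
    n_iter: int = 20,
    edge_pad: int = 30,
) -> np.ndarray:
    """Asymmetric-least-squares baseline estimate.

    Minimizes sum(w_i (y_i - z_i)^2) + smoothness * sum((d2 z)^2) with
    weights w_i = asymmetry for points above the baseline and 1 - asymmetry
    below, re-estimated over ``n_iter`` passes.  Larger ``smoothness``
    yields a stiffer (lower-curvature) baseline.  The spectrum is extended
    at both ends by linear extrapolation over ``edge_pad`` channels before
    solving, so the free-boundary flattening of the smoothness penalty
    falls outside the returned range.
    """
    y = np.asarray(intensities, dtype=float)
    if y.ndim != 1:
        raise ValueError("intensities must be 1-D")
    if not np.all(np.isfinite(y)):
        raise ValueError("intensities must be finite")
    n = y.size
    if n < 10:
        raise ValueError("baseline estimation needs >= 10 channels")
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    if not (0 < asymmetry < 1):
        raise ValueError("asymmetry must lie in (0, 1)")
    pad = int(min(edge_pad, n // 3))
    if pad > 0:
        # slopes from a short least-squares fit at each end
        k = min(10, n // 2)
        x = np.arange(k, dtype=float)
        sl_lo = np.polyfit(x, y[:k], 1)[0]
        sl_hi = np.polyfit(x, y[-k:], 1)[0]
        left = y[0] - sl_lo * np.arange(pad, 0, -1)
        right = y[-1] + sl_hi * np.arange(1, pad + 1)
        y_ext = np.concatenate([left, y, right])
    else:
        y_ext = y
    m = y_ext.size
    d0, d1, d2 = _second_diff_penalty_diagonals(m)
    ab = np.zeros((3, m))
    ab[1, : m - 1] = smoothness * d1
    ab[2, : m - 2] = smoothness * d2
    w = np.ones(m)
    z = y_ext
    for _ in range(n_iter):
        ab[0] = smoothness * d0 + w
        z = solveh_banded(ab, w * y_ext, lower=True)
        w_new = np.where(y_ext > z, asymmetry, 1.0 - asymmetry)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z[pad : pad + n] if pad > 0 else z


def baseline_correct(
    spectrum: Spectrum,
    smoothness: float = 1e4,
    asymmetry: float = 0.02,
    n_iter: int = 20,
) -> Spectrum:
    """Subtract the asymmetric-least-squares baseline estimate."""
    z = estimate_baseline(spectrum.intensities, smoothness, asymmetry, n_iter)
    return Spectrum(spectrum.axis, spectrum.intensities - z)


# ---------------------------------------------------------------------------
# peak height and map reduction
# ---------------------------------------------------------------------------


def _window_mask(axis: np.ndarray, center: float, halfwidth: float) -> np.ndarray:
    if halfwidth <= 0:
        # degenerate window: the single channel nearest to the band center
        mask = np.zeros(axis.size, dtype=bool)
        mask[int(np.argmin(np.abs(axis - center)))] = True
        return mask
    mask = np.abs(axis - center) <= halfwidth
    if not mask.any():
        raise ValueError(f"no channels within {halfwidth} cm^-1 of {center} cm^-1")
    return mask


def peak_height(spectrum: Spectrum, band: float, halfwidth: float = 10.0) -> float:
    """Maximum intensity inside ``band +/- halfwidth`` (assumes corrected input)."""
    mask = _window_mask(spectrum.axis, band, halfwidth)
    return float(spectrum.intensities[mask].max())


def map_reduce_top_fraction(
    smap: SpectralMap, config: Optional[ReductionConfig] = None
) -> MapReduction:
    """Collapse a chip map to one spectrum by top-fraction pixel averaging.

    Each pixel is cropped and (optionally) background-corrected, pixels are
    ranked by their peak height inside the target-band window, and the
    channelwise mean of the brightest ``ceil(fraction * n_pixels)`` pixels is
    returned together with the scalar mean peak height of those pixels.
    Ties in peak height break deterministically toward the lower pixel index.
    """
    if config is None:
        config = ReductionConfig()
    n = smap.n_pixels
    k = max(1, math.ceil(config.fraction * n))
    axis_out: Optional[np.ndarray] = None
    heights = np.empty(n)
    rows = []
    for i in range(n):
        spec = crop(smap.pixel(i), config.crop_range)
        if config.correct_baseline:
            spec = baseline_correct(
                spec, config.baseline_smoothness, config.baseline_asymmetry
            )
        rows.append(spec.intensities)
        axis_out = spec.axis
        heights[i] = peak_height(spec, config.target_band, config.window_halfwidth)
    matrix = np.vstack(rows)
    order = np.argsort(-heights, kind="stable")
    selected = np.sort(order[:k])
    mean_spectrum = matrix[selected].mean(axis=0)
    return MapReduction(
        spectrum=Spectrum(axis_out, mean_spectrum),
        peak_height=float(heights[selected].mean()),
        selected=selected,
        pixel_heights=heights,
    )


# ---------------------------------------------------------------------------
# signal-to-noise ratio
# ---------------------------------------------------------------------------


def snr(
    spectrum: Spectrum,
    signal_band: float = TARGET_BAND_CM1,
    noise_region: Tuple[float, float] = (1700.0, 1800.0),
    halfwidth: float = 10.0,
    correct_baseline: bool = True,
    smoothness: float = 1e4,
    asymmetry: float = 0.02,
) -> float:
    """Net peak height at the signal band over the noise-region intensity SD.

    The noise region must contain at least 5 channels and should exclude all
    analyte and interferent bands.  A zero noise SD is flagged as undefined
    (raises) rather than returned as infinity.
    """
    work = (
        baseline_correct(spectrum, smoothness, asymmetry)
        if correct_baseline
        else spectrum
    )
    h = peak_height(work, signal_band, halfwidth)
    lo, hi = noise_region
    mask = (work.axis >= lo) & (work.axis <= hi)
    if mask.sum() < 5:
        raise ValueError("noise region must contain at least 5 channels")
    sd = float(work.intensities[mask].std(ddof=1))
    if sd == 0:
        raise ValueError("noise SD is zero; SNR undefined")
    return h / sd


# ---------------------------------------------------------------------------
# dataset-level scaling / transforms
# ---------------------------------------------------------------------------

SCALING_METHODS = (
    "minmax",
    "autoscale",
    "meancenter",
    "vector_norm",
    "savgol_derivative",
    "log",
)


class Scaler:
    """Fit-on-train / apply-unchanged dataset scaling.

    Column-wise methods (``minmax``, ``autoscale``, ``meancenter``) store
    their training statistics and apply them unchanged to prediction rows.
    Row-wise transforms (``vector_norm``, ``savgol_derivative``, ``log``)
    are stateless.  ``minmax`` maps each training column onto [0, 1]; a
    constant column maps to 0.  ``autoscale`` raises on a zero-variance
    column rather than silently patching the division.
    """

    def __init__(
        self,
        method: str = "minmax",
        savgol_window: int = 9,
        savgol_polyorder: int = 2,
        savgol_deriv: int = 1,
    ) -> None:
        if method not in SCALING_METHODS:
            raise ValueError(f"unknown scaling method {method!r}; choose from {SCALING_METHODS}")
        self.method = method
        self.savgol_window = savgol_window
        self.savgol_polyorder = savgol_polyorder
        self.savgol_deriv = savgol_deriv
        self.offset_: Optional[np.ndarray] = None
        self.column_scale_: Optional[np.ndarray] = None  # per-column divisor

    def fit(self, X: np.ndarray) -> "Scaler":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.size == 0:
            raise ValueError("cannot fit a scaler on an empty matrix")
        if self.method == "minmax":
            mn = X.min(axis=0)
            rng = X.max(axis=0) - mn
            rng = np.where(rng == 0, 1.0, rng)  # constant column -> 0 after shift
            self.offset_, self.column_scale_ = mn, rng
        elif self.method == "autoscale":
            mu = X.mean(axis=0)
            sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
            if np.any(sd == 0):
                j = int(np.flatnonzero(sd == 0)[0])
                raise ValueError(f"autoscale undefined: column {j} has zero variance")
            self.offset_, self.column_scale_ = mu, sd
        elif self.method == "meancenter":
            self.offset_ = X.mean(axis=0)
            self.column_scale_ = np.ones(X.shape[1])
        # row-wise methods have no fitted state
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.method in ("minmax", "autoscale", "meancenter"):
            if self.offset_ is None:
                raise RuntimeError("scaler not fitted")
            return (X - self.offset_) / self.column_scale_
        if self.method == "vector_norm":
            norms = np.linalg.norm(X, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            return X / norms
        if self.method == "savgol_derivative":
            return savgol_filter(
                X,
                window_length=self.savgol_window,
                polyorder=self.savgol_polyorder,
                deriv=self.savgol_deriv,
                axis=1,
            )
        # log: clip negatives to zero, then log1p
        return np.log1p(np.clip(X, 0.0, None))

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    @property
    def is_column_linear(self) -> bool:
        """True when the transform is x -> (x - offset) / scale per column."""
        return self.method in ("minmax", "autoscale", "meancenter")


def scale_dataset(X: np.ndarray, method: str = "minmax", **kwargs) -> Tuple[np.ndarray, Scaler]:
    """Scale a training matrix; returns the scaled matrix and the fitted scaler."""
    scaler = Scaler(method, **kwargs)
    return scaler.fit_transform(X), scaler
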