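"""Core in-memory containers shared across the pipeline.

A :class:`Spectrum` is one intensity vector on a strictly increasing
wavenumber axis (cm^-1).  A :class:`SpectralMap` is the pixel-indexed
collection of spectra acquired by scanning one SERS chip.  A
:class:`CalibrationDataset` is the sample x channel matrix fed to the
calibration models, with concentrations in uM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["Spectrum", "SpectralMap", "CalibrationDataset", "PairedCohort"]


@dataclass
class Spectrum:
    """One spectrum: intensities (arbitrary instrument units) on a wavenumber axis."""

    axis: np.ndarray  # cm^-1, strictly increasing
    intensities: np.ndarray  # same length as axis

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.axis.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("axis and intensities must be 1-D")
        if self.axis.shape != self.intensities.shape:
            raise ValueError(
                f"axis length {self.axis.size} != intensities length {self.intensities.size}"
            )
        if self.axis.size >= 2 and not np.all(np.diff(self.axis) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")

    def __len__(self) -> int:
        return self.axis.size

    def copy(self) -> "Spectrum":
        return Spectrum(self.axis.copy(), self.intensities.copy())


@dataclass
class SpectralMap:
    """Pixel-indexed spectra from one chip scan; all pixels share one axis."""

    axis: np.ndarray
    intensities: np.ndarray  # (n_pixels, n_channels)
    coordinates: np.ndarray  # (n_pixels, 2) integer (row, col) grid positions
    map_id: str = "map0"

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=int))
        if self.intensities.shape[0] < 1:
            raise ValueError("a SpectralMap needs at least one pixel")
        if self.intensities.shape[1] != self.axis.size:
            raise ValueError("pixel spectra do not match the axis length")
        if self.coordinates.shape != (self.intensities.shape[0], 2):
            raise ValueError("coordinates must be (n_pixels, 2)")

    @property
    def n_pixels(self) -> int:
        return self.intensities.shape[0]

    def pixel(self, i: int) -> Spectrum:
        return Spectrum(self.axis, self.intensities[i])


@dataclass
class CalibrationDataset:
    """Sample x channel matrix X with concentrations y (uM) and row metadata."""

    X: np.ndarray  # (n_samples, n_channels)
    y: np.ndarray  # (n_samples,) concentrations, uM
    axis: np.ndarray  # (n_channels,) cm^-1
    metadata: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.X.shape[0] != self.y.size:
            raise ValueError(f"X has {self.X.shape[0]} rows but y has {self.y.size} entries")
        if self.X.shape[1] != self.axis.size:
            raise ValueError("X columns do not match the axis length")
        if np.any(self.y < 0):
            raise ValueError("concentrations must be non-negative")
        if self.metadata is not None and len(self.metadata) != self.X.shape[0]:
            raise ValueError("metadata rows do not match X rows")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def groups(self) -> np.ndarray:
        """Cross-validation group label per row.

        Replicates of the same concentration level are kept together (same
        label) so that no level leaks between calibration and validation
        folds.  Falls back to the concentration values themselves when no
        metadata is attached.
        """
        if self.metadata is not None and "concentration_uM" in self.metadata:
            return self.metadata["concentration_uM"].to_numpy()
        return self.y.copy()


@dataclass
class PairedCohort:
    """Paired reference/test concentration series with known ground truth (uM)."""

    truth: np.ndarray
    reference: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        self.truth = np.asarray(self.truth, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        self.test = np.asarray(self.test, dtype=float)
        if not (self.truth.shape == self.reference.shape == self.test.shape):
            raise ValueError("truth, reference and test must have equal length")

    @property
    def n_pairs(self) -> int:
        return self.truth.size
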