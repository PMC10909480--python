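"""Shared containers and conventions.

Conventions used throughout the package:

* Rasters are 2D ``numpy`` arrays of shape ``(ny, nx)`` indexed
  ``[row, col]`` with **row 0 at the bottom** (mathematical orientation).
  The physical centre of pixel ``(i, j)`` is
  ``x = (j + 0.5) * pixel_size_um``, ``y = (i + 0.5) * pixel_size_um``,
  origin at the image lower-left corner.
* Labels: 0 = stroma, 1 = epithelial compartment, 2 = acinar lumen.
  Every pixel is tissue; there is no background label.
* Angles are axial (headless fibre directions, theta == theta + 180deg),
  in degrees, counter-clockwise from the image x-axis, normalized to
  ``[-90, 90)``.  Undefined orientations are ``nan``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

STROMA = 0
EPITHELIUM = 1
LUMEN = 2
VALID_LABELS = (STROMA, EPITHELIUM, LUMEN)
LABEL_NAMES = {STROMA: "stroma", EPITHELIUM: "epithelium", LUMEN: "lumen"}


def wrap_axial_deg(angle_deg):
    """Normalize axial angles (degrees) to the canonical range [-90, 90)."""
    a = np.asarray(angle_deg, dtype=float)
    wrapped = np.mod(a + 90.0, 180.0) - 90.0
    # mod can land exactly on +90 through rounding; fold it back
    wrapped = np.where(wrapped >= 90.0, wrapped - 180.0, wrapped)
    if np.isscalar(angle_deg) or np.ndim(angle_deg) == 0:
        return float(wrapped)
    return wrapped


def axial_difference_deg(a_deg, b_deg):
    """Smallest unsigned difference between two axial angles, in [0, 90]."""
    d = np.abs(np.mod(np.asarray(a_deg, float) - np.asarray(b_deg, float), 180.0))
    d = np.minimum(d, 180.0 - d)
    if np.ndim(d) == 0:
        return float(d)
    return d


@dataclass
class LabelImage:
    """Integer-labelled three-phase raster with a physical pixel size."""

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D raster")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(self.labels == self.labels.astype(np.int64)):
                raise ValueError("labels must be integers")
            self.labels = self.labels.astype(np.uint8)
        bad = np.setdiff1d(np.unique(self.labels), VALID_LABELS)
        if bad.size:
            idx = np.argwhere(self.labels == bad[0])[0]
            raise ValueError(
                f"unknown label {int(bad[0])} at pixel (row={int(idx[0])}, "
                f"col={int(idx[1])})"
            )
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        self.pixel_size_um = float(self.pixel_size_um)

    @property
    def shape(self):
        return self.labels.shape

    def phase_mask(self, label: int) -> np.ndarray:
        if label not in VALID_LABELS:
            raise ValueError(f"unknown label {label}")
        return self.labels == label


@dataclass
class GreyImage:
    """Greyscale intensity raster in [0, 1] with a physical pixel size."""

    intensities: np.ndarray
    pixel_size_um: float

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2D raster")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.intensities.min() < 0 or self.intensities.max() > 1:
            raise ValueError("intensities must lie within [0, 1]")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        self.pixel_size_um = float(self.pixel_size_um)


@dataclass
class OrientationMap:
    """Per-pixel axial fibre angles on the stromal support.

    ``angle_deg`` is nan outside the stromal phase (the explicit
    "undefined" marker); ``coherence`` in [0, 1] measures how directed
    the local structure is (0 = isotropic, 1 = perfectly oriented).
    """

    angle_deg: np.ndarray
    coherence: np.ndarray
    window_px: int
    pixel_size_um: float

    def __post_init__(self):
        self.angle_deg = np.asarray(self.angle_deg, dtype=float)
        self.coherence = np.asarray(self.coherence, dtype=float)
        if self.angle_deg.shape != self.coherence.shape:
            raise ValueError("angle and coherence rasters must share a shape")
        defined = np.isfinite(self.angle_deg)
        a = self.angle_deg[defined]
        if a.size and (a.min() < -90.0 or a.max() >= 90.0):
            raise ValueError("defined angles must lie in [-90, 90)")
        c = self.coherence[defined]
        if c.size and (c.min() < 0 or c.max() > 1):
            raise ValueError("coherence must lie in [0, 1]")
        self.window_px = int(self.window_px)
        self.pixel_size_um = float(self.pixel_size_um)

    @property
    def shape(self):
        return self.angle_deg.shape

    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.angle_deg)


def pixel_centres_um(shape, pixel_size_um):
    """Physical (x, y) coordinate rasters of pixel centres."""
    ny, nx = shape
    x = (np.arange(nx) + 0.5) * pixel_size_um
    y = (np.arange(ny) + 0.5) * pixel_size_um
    return np.meshgrid(x, y)
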