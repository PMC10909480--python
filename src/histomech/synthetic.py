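"""Seeded synthetic three-phase glandular microstructures.

Normal glandular (prostate-like) tissue in cross-section shows roughly
elliptical acini -- a bright lumen wrapped by a dark epithelial ring --
embedded in a connected fibromuscular stromal matrix.  The generator
emulates exactly that motif: elliptical lumen cores with an epithelial
ring of fixed physical thickness, placed by dart throwing with a hard
non-overlap constraint on a stromal background.  Structural anisotropy
is controlled by the acinus elongation (major/minor axis ratio) and a
preferred orientation with Gaussian dispersion.

Everything is deterministic given (spec, seed): the same spec produces a
bit-identical raster and ground truth.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy import ndimage

from .core import (
    LabelImage,
    OrientationMap,
    STROMA,
    EPITHELIUM,
    LUMEN,
    wrap_axial_deg,
    pixel_centres_um,
)

MAX_DART_ATTEMPTS = 10_000


class InfeasibleSpecError(RuntimeError):
    """Raised when the requested packing cannot be realized."""


@dataclass
class MicrostructureSpec:
    """Parameters of a synthetic glandular microstructure.

    Lengths are in micrometres; ``elongation`` is the major/minor axis
    ratio of the acini (>= 1); ``preferred_angle_deg`` the mean acinar
    major-axis direction; ``angle_dispersion_deg`` the s.d. of the
    per-acinus orientation about it.
    """

    width_px: int = 256
    height_px: int = 256
    pixel_size_um: float = 2.0
    n_acini: int = 12
    lumen_radius_mean_um: float = 30.0
    lumen_radius_sd_um: float = 6.0
    epithelium_thickness_um: float = 12.0
    elongation: float = 1.5
    preferred_angle_deg: float = 0.0
    angle_dispersion_deg: float = 10.0
    min_gap_um: float | None = None   # stromal channel width between acini
    seed: int = 0

    def __post_init__(self):
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_acini < 0:
            raise ValueError("n_acini must be nonnegative")
        if self.lumen_radius_mean_um <= 0 or self.lumen_radius_sd_um <= 0:
            raise ValueError("lumen radius parameters must be positive")
        if self.epithelium_thickness_um <= 0:
            raise ValueError("epithelium_thickness_um must be positive")
        if self.elongation < 1:
            raise ValueError("elongation must be >= 1")
        if not (-90.0 <= self.preferred_angle_deg < 90.0):
            raise ValueError("preferred_angle_deg must lie in [-90, 90)")
        if self.angle_dispersion_deg < 0:
            raise ValueError("angle_dispersion_deg must be nonnegative")
        area = self.width_px * self.height_px * self.pixel_size_um**2
        r_out = self.lumen_radius_mean_um + self.epithelium_thickness_um
        # mean acinus outer area; elongation stretches one axis and
        # shrinks none, so e * pi * r_out^2 bounds it from above
        if self.n_acini * np.pi * self.elongation * r_out**2 > area:
            raise InfeasibleSpecError(
                "requested acini cannot fit: "
                f"{self.n_acini} x pi x {self.elongation:.2f} x "
                f"{r_out:.1f}^2 um^2 exceeds the image area {area:.1f} um^2"
            )


@dataclass
class GroundTruth:
    """Exact generation record for a synthetic microstructure."""

    area_fractions: tuple  # (stroma, epithelium, lumen), sums to 1
    acinus_centres_um: list
    acinus_axes_um: list  # (semi-major, semi-minor) of the lumen core
    acinus_angles_deg: list
    true_preferred_angle_deg: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _support_radius(a: float, b: float, angle_deg: float, direction_deg: float) -> float:
    """Support function of an origin-centred ellipse in a given direction."""
    phi = np.deg2rad(direction_deg - angle_deg)
    return float(np.sqrt((a * np.cos(phi)) ** 2 + (b * np.sin(phi)) ** 2))


def _paint_ellipse(labels, cx, cy, a, b, angle_deg, value, pixel_size):
    """Set pixels whose centres fall inside the ellipse to ``value``."""
    X, Y = pixel_centres_um(labels.shape, pixel_size)
    t = np.deg2rad(angle_deg)
    dx, dy = X - cx, Y - cy
    u = dx * np.cos(t) + dy * np.sin(t)
    v = -dx * np.sin(t) + dy * np.cos(t)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    labels[inside] = value


def generate_microstructure(spec: MicrostructureSpec):
    """Generate a three-phase label image and its exact ground truth.

    Acini (lumen core + epithelial ring) are ellipses placed by dart
    throwing with a conservative separating-line non-overlap test; the
    stromal matrix is the complement and is kept 4-connected by placing
    acini fully interior to the raster.

    Returns
    -------
    (LabelImage, GroundTruth)

    Raises
    ------
    InfeasibleSpecError
        If an acinus cannot be placed within the attempt budget.
    """
    rng = np.random.default_rng(spec.seed)
    W = spec.width_px * spec.pixel_size_um
    H = spec.height_px * spec.pixel_size_um
    t_epi = spec.epithelium_thickness_um
    # minimum stromal channel between acini (and to the border), wide
    # enough that the stromal matrix stays 4-connected at pixel scale
    gap = spec.min_gap_um if spec.min_gap_um is not None else \
        max(3.0 * spec.pixel_size_um, 0.5 * t_epi)

    centres, axes, angles = [], [], []
    for k in range(spec.n_acini):
        placed = False
        for _ in range(MAX_DART_ATTEMPTS):
            r = -1.0
            while r <= spec.pixel_size_um:  # lumen core at least one pixel
                r = rng.normal(spec.lumen_radius_mean_um, spec.lumen_radius_sd_um)
            a_lum = spec.elongation * r  # semi-major
            b_lum = r                    # semi-minor
            if spec.angle_dispersion_deg > 0:
                ang = wrap_axial_deg(
                    spec.preferred_angle_deg
                    + rng.normal(0.0, spec.angle_dispersion_deg)
                )
            else:
                ang = spec.preferred_angle_deg
            a_out, b_out = a_lum + t_epi, b_lum + t_epi
            margin_x = _support_radius(a_out, b_out, ang, 0.0) + gap
            margin_y = _support_radius(a_out, b_out, ang, 90.0) + gap
            if 2 * margin_x >= W or 2 * margin_y >= H:
                continue
            cx = rng.uniform(margin_x, W - margin_x)
            cy = rng.uniform(margin_y, H - margin_y)
            ok = True
            for (ox, oy), (oa, ob), oang in zip(centres, axes, angles):
                oa_out, ob_out = oa + t_epi, ob + t_epi
                d = np.hypot(cx - ox, cy - oy)
                line = np.rad2deg(np.arctan2(cy - oy, cx - ox))
                if d <= gap + (
                    _support_radius(a_out, b_out, ang, line)
                    + _support_radius(oa_out, ob_out, oang, line)
                ):
                    ok = False
                    break
            if ok:
                centres.append((cx, cy))
                axes.append((a_lum, b_lum))
                angles.append(float(ang))
                placed = True
                break
        if not placed:
            raise InfeasibleSpecError(
                f"could not place acinus {k + 1}/{spec.n_acini} within "
                f"{MAX_DART_ATTEMPTS} attempts"
            )

    labels = np.full((spec.height_px, spec.width_px), STROMA, dtype=np.uint8)
    for (cx, cy), (a_lum, b_lum), ang in zip(centres, axes, angles):
        _paint_ellipse(labels, cx, cy, a_lum + t_epi, b_lum + t_epi, ang,
                       EPITHELIUM, spec.pixel_size_um)
    for (cx, cy), (a_lum, b_lum), ang in zip(centres, axes, angles):
        _paint_ellipse(labels, cx, cy, a_lum, b_lum, ang, LUMEN,
                       spec.pixel_size_um)

    image = LabelImage(labels, spec.pixel_size_um)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    if ndimage.label(labels == STROMA, structure=structure)[1] != 1:
        raise InfeasibleSpecError(
            "stromal phase is not a single connected component")

    truth = GroundTruth(
        area_fractions=area_fractions(image),
        acinus_centres_um=[list(c) for c in centres],
        acinus_axes_um=[list(a) for a in axes],
        acinus_angles_deg=angles,
        true_preferred_angle_deg=float(spec.preferred_angle_deg),
    )
    return image, truth


def area_fractions(label: LabelImage):
    """Per-phase pixel fractions (stroma, epithelium, lumen); sums to 1."""
    n = label.labels.size
    counts = np.bincount(label.labels.ravel(), minlength=3)[:3]
    return tuple(float(c) / n for c in counts)


def generate_fiber_field(label: LabelImage, mode="channel_tangent",
                         angle_deg: float | None = None,
                         smoothing_px: float = 3.0) -> OrientationMap:
    """Assign a collagen-fibre direction to every stromal pixel.

    ``constant`` writes ``angle_deg`` everywhere on the stromal support.
    ``channel_tangent`` orients fibres along the stromal channels: at
    each stromal pixel the direction perpendicular to the gradient of
    the (smoothed) distance-to-non-stroma transform.  Non-stromal pixels
    carry nan.
    """
    stroma = label.phase_mask(STROMA)
    if not stroma.any():
        raise ValueError("no stromal pixels: fibre field undefined")
    angle = np.full(label.shape, np.nan)
    if mode == "constant":
        if angle_deg is None:
            raise ValueError("constant mode requires angle_deg")
        angle[stroma] = wrap_axial_deg(angle_deg)
        coherence = np.where(stroma, 1.0, 0.0)
    elif mode == "channel_tangent":
        dist = ndimage.distance_transform_edt(stroma)
        dist = ndimage.gaussian_filter(dist, smoothing_px)
        gy, gx = np.gradient(dist)  # axis 0 is y (row 0 at bottom)
        tangent = np.rad2deg(np.arctan2(gy, gx)) + 90.0
        angle[stroma] = wrap_axial_deg(tangent[stroma])
        mag = np.hypot(gx, gy)
        coherence = np.where(stroma, np.minimum(mag / (mag.max() + 1e-30), 1.0), 0.0)
    else:
        raise ValueError(f"unknown fibre-field mode {mode!r}")
    return OrientationMap(angle, coherence, window_px=1,
                         pixel_size_um=label.pixel_size_um)
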