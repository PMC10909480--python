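"""Mean-intercept-length (MIL) fabric analysis of a binary phase mask.

For each sampled direction, parallel test lines are drawn across the
raster and the mean length of foreground runs along them is recorded:
MIL(theta) = total foreground length traversed / number of foreground
runs intersected.  Plotting L(theta)*u(theta) and its antipode for all
directions gives a point cloud whose shape summarizes the structural
anisotropy of the phase; an origin-centred ellipse is fitted to it and
the degree of anisotropy is

    DA = 1 - a^2 / b^2,    a <= b the fitted radii,

so DA = 0 for structural isotropy and DA = 1 for full anisotropy.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LabelImage, wrap_axial_deg

_SAMPLE_STEP_PX = 0.5  # along-line sampling step


@dataclass
class MILPointCloud:
    points: np.ndarray          # (2 * n_used, 2), um; closed under negation
    directions_used: int
    line_spacing_px: float
    seed: int
    degenerate: bool = False    # full-foreground mask: no interfaces

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)


@dataclass
class EllipseFit:
    a_um: float                 # minor radius
    b_um: float                 # major radius
    angle_deg: float            # major-axis direction, [-90, 90)
    isotropic: bool = False     # a == b to fit precision: angle arbitrary
    degenerate: bool = False    # collinear cloud: a = 0

    def __post_init__(self):
        if not (0.0 <= self.a_um <= self.b_um):
            raise ValueError("ellipse radii must satisfy 0 <= a <= b")
        self.angle_deg = wrap_axial_deg(self.angle_deg)


@dataclass
class FabricResult:
    fit: EllipseFit
    DA: float


def mean_intercept_lengths(mask, pixel_size_um: float = 1.0,
                           n_directions: int = 180,
                           line_spacing_px: float = 1.0,
                           seed: int = 0,
                           offset_rad: float | None = None) -> MILPointCloud:
    """Sample the MIL point cloud of a binary mask.

    Directions are ``n_directions`` values uniform on [0, pi) plus one
    shared rotational offset (random from ``seed`` unless given
    explicitly).  For every direction, parallel lines at
    ``line_spacing_px`` are traversed at a half-pixel step; each maximal
    stretch of consecutive foreground samples on a line counts as one
    run.  Runs shorter than two pixels are discarded: the staircase of a
    rasterized boundary sheds spurious sub-pixel runs that otherwise
    drag the fitted principal axis toward the raster axes.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2D raster")
    if not mask.any():
        raise ValueError("empty-foreground mask: MIL undefined")
    if n_directions < 8:
        raise ValueError("need at least 8 sampling directions")
    degenerate = bool(mask.all())
    min_samples = int(np.ceil(2.0 / _SAMPLE_STEP_PX))  # 2 px worth

    ny, nx = mask.shape
    if offset_rad is None:
        rng = np.random.default_rng(seed)
        offset_rad = rng.uniform(0.0, np.pi / n_directions)
    thetas = offset_rad + np.arange(n_directions) * (np.pi / n_directions)

    diag = float(np.hypot(nx, ny))
    cx, cy = nx / 2.0, ny / 2.0
    line_offsets = np.arange(-diag / 2, diag / 2 + line_spacing_px,
                             line_spacing_px)
    t = np.arange(-diag / 2, diag / 2 + _SAMPLE_STEP_PX, _SAMPLE_STEP_PX)

    points = []
    used = 0
    pad = np.zeros((len(line_offsets), 1), dtype=np.int8)
    for theta in thetas:
        ux, uy = np.cos(theta), np.sin(theta)
        # line normal is (-uy, ux)
        px = cx + line_offsets[:, None] * (-uy) + t[None, :] * ux
        py = cy + line_offsets[:, None] * ux + t[None, :] * uy
        ix = np.floor(px).astype(np.int64)
        iy = np.floor(py).astype(np.int64)
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        fg = np.zeros(ix.shape, dtype=np.int8)
        fg[inside] = mask[iy[inside], ix[inside]]
        d = np.diff(np.concatenate([pad, fg, pad], axis=1), axis=1)
        run_lengths = np.nonzero(d.ravel() == -1)[0] \
            - np.nonzero(d.ravel() == 1)[0]
        run_lengths = run_lengths[run_lengths >= min_samples]
        if run_lengths.size == 0:
            continue  # spacing too coarse to hit the phase at this angle
        mil = (run_lengths.sum() * _SAMPLE_STEP_PX * pixel_size_um
               / run_lengths.size)
        points.append((mil * ux, mil * uy))
        points.append((-mil * ux, -mil * uy))
        used += 1
    if used == 0:
        raise ValueError("no test line intersected the foreground")
    return MILPointCloud(np.array(points), used, float(line_spacing_px),
                         int(seed), degenerate)


def fit_ellipse(cloud: MILPointCloud) -> EllipseFit:
    """Least-squares origin-centred ellipse through an MIL point cloud.

    Fits the symmetric positive-definite form x^T Q x = 1; the radii are
    the inverse square roots of the eigenvalues of Q.  A collinear cloud
    (rank-deficient fit) degenerates to a segment: a = 0 with the major
    axis along the points.
    """
    P = cloud.points
    if P.shape[0] < 8:
        raise ValueError("need at least 8 points (4 directions) to fit")
    x, y = P[:, 0], P[:, 1]
    D = np.column_stack([x**2, 2 * x * y, y**2])
    q, _, rank, _ = np.linalg.lstsq(D, np.ones(len(P)), rcond=None)
    Q = np.array([[q[0], q[1]], [q[1], q[2]]])
    evals, evecs = np.linalg.eigh(Q)
    if rank < 3 or evals[0] <= 0:
        # collinear cloud through the origin
        k = int(np.argmax(np.hypot(x, y)))
        angle = np.rad2deg(np.arctan2(y[k], x[k]))
        return EllipseFit(0.0, float(np.hypot(x[k], y[k])), angle,
                          degenerate=True)
    radii = evals ** -0.5           # ascending evals -> descending radii
    b_um, a_um = float(radii[0]), float(radii[1])
    v_major = evecs[:, 0]
    angle = np.rad2deg(np.arctan2(v_major[1], v_major[0]))
    isotropic = (b_um - a_um) <= 1e-8 * b_um
    if isotropic:
        angle = 0.0
    return EllipseFit(a_um, b_um, angle, isotropic=isotropic)


def degree_of_anisotropy(fit: EllipseFit) -> float:
    """DA = 1 - a^2/b^2; 0 = isotropic, 1 = fully anisotropic."""
    if fit.b_um == 0:
        raise ValueError("degenerate fit with b = 0: DA undefined")
    return 1.0 - fit.a_um**2 / fit.b_um**2


def principal_angle(fit: EllipseFit) -> float:
    """Major-axis direction in [-90, 90); 0 when isotropic (arbitrary)."""
    if fit.isotropic:
        return 0.0
    return fit.angle_deg


def fabric_analysis(label: LabelImage, phase: int,
                    n_directions: int = 180, line_spacing_px: float = 1.0,
                    seed: int = 0) -> FabricResult:
    """MIL fabric ellipse and degree of anisotropy of one phase mask."""
    cloud = mean_intercept_lengths(label.phase_mask(phase),
                                   pixel_size_um=label.pixel_size_um,
                                   n_directions=n_directions,
                                   line_spacing_px=line_spacing_px,
                                   seed=seed)
    fit = fit_ellipse(cloud)
    return FabricResult(fit, degree_of_anisotropy(fit))
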