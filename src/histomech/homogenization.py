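"""Pixel-based plane-stress FE homogenization with periodic boundary conditions.

The mirrored RVE raster is meshed one bilinear quadrilateral per
(coarsen x coarsen) pixel block, each element carrying a constituent
label and, for stromal elements, a local collagen-fibre angle.  Apparent
properties come from a first-order computational homogenization: the
displacement is split into a macroscopic part driven by the in-plane
displacement-gradient components H = (H11, H22, H12, H21), held on
macro reference DOFs, and a periodic fluctuation,

    u(x+) - u(x-) = H . (x+ - x-)

on paired opposite-boundary nodes.  Three tests (uniaxial along 1 and 2,
simple shear 12), each at +/-5% global strain, are solved with an
incremental Newton-Raphson on the total-Lagrangian equilibrium; the
volume-averaged Cauchy stress yields six secant moduli
(E11, E22, G12 in tension and compression).

By default the "uniaxial" tests are uniaxial *macro stress*: the
prescribed normal strain is applied while the transverse normal
component of H is left free with zero conjugate macro force, making
<sigma11>/eps directly comparable to an indentation-style Young's
modulus.  Setting ``transverse="fixed"`` prescribes the full macro
strain instead.

Quadrature is plain 2x2 Gauss: under the plane-stress contract the
out-of-plane stretch is condensed pointwise, so near-incompressibility
does not lock bilinear quadrilaterals and no selective integration is
needed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .core import LabelImage, OrientationMap, STROMA, EPITHELIUM, LUMEN
from .constitutive import condensed_response_batch, _params_arrays
from .rve import PeriodicRVE

_H_COMPONENTS = ("H11", "H22", "H12", "H21")


# ---------------------------------------------------------------------------
# mesh
# ---------------------------------------------------------------------------

@dataclass
class FEModel:
    """Structured bilinear-quad mesh on pixel blocks."""

    nodes: np.ndarray          # (n_nodes, 2) um
    elements: np.ndarray       # (n_el, 4) CCW connectivity
    labels: np.ndarray         # (n_el,) constituent per element
    angles_deg: np.ndarray     # (n_el,) fibre angle; nan for non-stroma
    nx: int                    # elements along x
    ny: int                    # elements along y
    h_um: float                # element edge length

    @property
    def n_nodes(self):
        return len(self.nodes)

    @property
    def n_elements(self):
        return len(self.elements)


def _axial_mean_deg(angles):
    a = np.deg2rad(angles[np.isfinite(angles)])
    if a.size == 0:
        return 0.0
    ang = 0.5 * np.arctan2(np.mean(np.sin(2 * a)), np.mean(np.cos(2 * a)))
    return float(np.rad2deg(ang))


def mesh_from_labels(rve, coarsen: int = 1) -> FEModel:
    """One quad element per pixel block, majority-vote labels.

    ``rve`` may be a PeriodicRVE or a bare LabelImage (then all-stroma
    elements get angle 0 unless an orientation map is attached).  Block
    label ties break stroma > epithelium > lumen; the stromal element
    angle is the orientation value at the block centre (falling back to
    the axial mean over the block).
    """
    if isinstance(rve, PeriodicRVE):
        label, omap = rve.labels, rve.orientation
    else:
        label, omap = rve, None
    ny_px, nx_px = label.shape
    if ny_px % coarsen or nx_px % coarsen:
        raise ValueError(
            f"coarsen={coarsen} does not divide the raster {ny_px}x{nx_px}")
    ny, nx = ny_px // coarsen, nx_px // coarsen
    blocks = label.labels.reshape(ny, coarsen, nx, coarsen)
    counts = np.stack([(blocks == l).sum(axis=(1, 3))
                       for l in (STROMA, EPITHELIUM, LUMEN)])
    elem_label = np.argmax(counts, axis=0).astype(np.uint8)  # first max wins

    angles = np.full((ny, nx), np.nan)
    if omap is not None:
        c2 = coarsen // 2
        centre = omap.angle_deg[c2::coarsen, c2::coarsen][:ny, :nx]
        angles = np.where(elem_label == STROMA, centre, np.nan)
        missing = (elem_label == STROMA) & ~np.isfinite(angles)
        if missing.any():
            amap = omap.angle_deg.reshape(ny, coarsen, nx, coarsen)
            for ei, ej in zip(*np.nonzero(missing)):
                angles[ei, ej] = _axial_mean_deg(amap[ei, :, ej, :].ravel())
    else:
        angles = np.where(elem_label == STROMA, 0.0, np.nan)

    h = coarsen * label.pixel_size_um
    xs = np.arange(nx + 1) * h
    ys = np.arange(ny + 1) * h
    X, Y = np.meshgrid(xs, ys)
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    ei, ej = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    n00 = ei * (nx + 1) + ej
    conn = np.stack([n00, n00 + 1, n00 + nx + 2, n00 + nx + 1],
                    axis=-1).reshape(-1, 4)
    return FEModel(nodes, conn, elem_label.ravel(), angles.ravel(),
                   nx, ny, float(h))


# ---------------------------------------------------------------------------
# periodic couplings
# ---------------------------------------------------------------------------

@dataclass
class PBCConstraints:
    """Slave-master node pairings u(x+) - u(x-) = H . (x+ - x-).

    Each boundary slave appears exactly once; the three non-master
    corners are all identified with the master corner.  For an Ne x Ne
    element grid this gives 2*(Ne - 1) edge pairs + 3 corner
    identifications.
    """

    pairs: list                # (slave_node, master_node)
    master_corner: int
    macro_components: tuple = _H_COMPONENTS

    def __post_init__(self):
        slaves = [s for s, _ in self.pairs]
        if len(slaves) != len(set(slaves)):
            dup = sorted({s for s in slaves if slaves.count(s) > 1})
            raise ValueError(
                f"redundant periodic constraint: node(s) {dup} appear as "
                "slave more than once (singular system)")
        if any(s == m for s, m in self.pairs):
            raise ValueError("a node cannot be paired with itself")


def periodic_couplings(model: FEModel) -> PBCConstraints:
    """Periodic node pairings of the structured boundary.

    Right column wraps onto the left, top row onto the bottom, and the
    three remaining corners onto the lower-left master corner.
    """
    nx, ny = model.nx, model.ny
    nid = lambda i, j: i * (nx + 1) + j
    pairs = []
    for i in range(1, ny):                       # edge pairs, no corners
        pairs.append((nid(i, nx), nid(i, 0)))
    for j in range(1, nx):
        pairs.append((nid(ny, j), nid(0, j)))
    master = nid(0, 0)
    for (i, j) in ((0, nx), (ny, 0), (ny, nx)):  # 3 corner identifications
        pairs.append((nid(i, j), master))
    return PBCConstraints(pairs, master)


def _transform_matrices(model: FEModel, pbc: PBCConstraints):
    """Sparse maps u_full = T_w w + T_H H (w excludes the pinned corner)."""
    n = model.n_nodes
    slave_of = dict(pbc.pairs)
    masters = [k for k in range(n) if k not in slave_of]
    red_index = {}
    col = 0
    for k in masters:
        if k == pbc.master_corner:
            red_index[k] = None  # pinned: u = H.x gauge
        else:
            red_index[k] = col
            col += 1
    n_w = col

    rows_w, cols_w, vals_w = [], [], []
    rows_h, cols_h, vals_h = [], [], []

    def add_H(node, ref_node):
        dx = model.nodes[node] - model.nodes[ref_node]
        # u_x gets H11*dx + H12*dy ; u_y gets H22*dy + H21*dx
        for comp, (hidx, d) in ((0, (0, dx[0])), (0, (2, dx[1])),
                                (1, (1, dx[1])), (1, (3, dx[0]))):
            if d != 0.0:
                rows_h.append(2 * node + comp)
                cols_h.append(hidx)
                vals_h.append(d)

    for k in range(n):
        m = slave_of.get(k, k)
        ridx = red_index[m]
        if ridx is not None:
            for comp in range(2):
                rows_w.append(2 * k + comp)
                cols_w.append(2 * ridx + comp)
                vals_w.append(1.0)
        if k != m:
            add_H(k, m)

    T_w = sparse.csr_matrix((vals_w, (rows_w, cols_w)), shape=(2 * n, 2 * n_w))
    T_H = sparse.csr_matrix((vals_h, (rows_h, cols_h)), shape=(2 * n, 4))
    return T_w, T_H


# ---------------------------------------------------------------------------
# load cases
# ---------------------------------------------------------------------------

@dataclass
class MacroLoadCase:
    """One homogenization test: uniaxial-1, uniaxial-2 or shear-12."""

    kind: str                  # 'uniaxial-1' | 'uniaxial-2' | 'shear-12'
    sign: int = +1
    magnitude: float = 0.05    # engineering strain
    transverse: str = "free"   # 'free' = uniaxial macro stress, 'fixed'

    def __post_init__(self):
        if self.kind not in ("uniaxial-1", "uniaxial-2", "shear-12"):
            raise ValueError(f"unknown load case kind {self.kind!r}")
        if self.sign not in (-1, +1):
            raise ValueError("sign must be +1 or -1")
        if not (self.magnitude > 0):
            raise ValueError("magnitude must be positive")
        if self.transverse not in ("free", "fixed"):
            raise ValueError("transverse must be 'free' or 'fixed'")

    def prescribed(self):
        """(index -> value) over H = (H11, H22, H12, H21)."""
        m = self.sign * self.magnitude
        if self.kind == "uniaxial-1":
            p = {0: m, 2: 0.0, 3: 0.0}
            if self.transverse == "fixed":
                p[1] = 0.0
        elif self.kind == "uniaxial-2":
            p = {1: m, 2: 0.0, 3: 0.0}
            if self.transverse == "fixed":
                p[0] = 0.0
        else:  # symmetric H12 = H21 avoids macro rotation; gamma = magnitude
            p = {2: m / 2.0, 3: m / 2.0}
            if self.transverse == "fixed":
                p[0] = 0.0
                p[1] = 0.0
        return p


@dataclass
class CaseResult:
    case: MacroLoadCase
    H: np.ndarray                  # converged macro components (4,)
    mean_cauchy: np.ndarray        # deformed-volume average, (2, 2) kPa
    mean_pk1: np.ndarray           # reference-volume average, (2, 2) kPa
    macro_reaction: np.ndarray     # T_H^T g / V0, (2, 2) kPa
    hill_mandel_rel: float
    residual_history: list
    u: np.ndarray = field(repr=False, default=None)  # full nodal field


class NewtonDivergence(RuntimeError):
    def __init__(self, msg, residual_history):
        super().__init__(msg)
        self.residual_history = residual_history


def _material_arrays(model: FEModel, materials: dict):
    out = []
    for name in ("C10", "D1", "k1", "k2", "kappa"):
        out.append(np.empty(model.n_elements))
    C10, D1, k1, k2, kappa = out
    for lab in np.unique(model.labels):
        if lab not in materials:
            raise ValueError(f"no material defined for label {int(lab)}")
        vals = _params_arrays(materials[lab])
        sel = model.labels == lab
        for arr, v in zip(out, vals):
            arr[sel] = v
    ang = np.where(np.isfinite(model.angles_deg), model.angles_deg, 0.0)
    return C10, D1, k1, k2, kappa, ang


def _shape_gradients(h):
    """dN/dX (4, 2) at the four 2x2 Gauss points of a square element."""
    g = 1.0 / np.sqrt(3.0)
    pts = [(-g, -g), (g, -g), (g, g), (-g, g)]
    grads = []
    for xi, eta in pts:
        dN = np.array([
            [-(1 - eta), -(1 - xi)],
            [+(1 - eta), -(1 + xi)],
            [+(1 + eta), +(1 + xi)],
            [-(1 + eta), +(1 - xi)],
        ]) / 4.0
        grads.append(dN * 2.0 / h)
    return np.array(grads)   # (4 gp, 4 nodes, 2)


class _Assembler:
    """Vectorized residual/stiffness assembly over all quadrature points."""

    def __init__(self, model: FEModel, materials: dict):
        self.model = model
        C10, D1, k1, k2, kappa, ang = _material_arrays(model, materials)
        self.n_gp = 4
        rep = lambda a: np.repeat(a[:, None], self.n_gp, axis=1)
        self.C10, self.D1 = rep(C10), rep(D1)
        self.k1, self.k2, self.kappa = rep(k1), rep(k2), rep(kappa)
        self.ang = rep(ang)
        self.grads = _shape_gradients(model.h_um)      # (gp, 4, 2)
        self.wdet = model.h_um**2 / 4.0                # weight * detJac
        self.lam3 = np.ones((model.n_elements, self.n_gp))
        conn = model.elements
        dofs = np.empty((model.n_elements, 8), dtype=np.int64)
        dofs[:, 0::2] = 2 * conn
        dofs[:, 1::2] = 2 * conn + 1
        self.dofs = dofs
        self.rows = np.repeat(dofs, 8, axis=1).ravel()
        self.cols = np.tile(dofs, (1, 8)).ravel()

    def response(self, u_full, with_stiffness=True):
        m = self.model
        u_el = u_full.reshape(-1, 2)[m.elements]            # (el, 4, 2)
        F = np.broadcast_to(np.eye(2), (m.n_elements, self.n_gp, 2, 2)).copy()
        F += np.einsum("eai,gaJ->egiJ", u_el, self.grads)
        lam3, P, Ahat, Wden = condensed_response_batch(
            F, self.ang, self.C10, self.D1, self.k1, self.k2, self.kappa,
            lam3_init=self.lam3, need_tangent=with_stiffness)
        self.lam3 = lam3
        f_el = self.wdet * np.einsum("egiJ,gaJ->eai", P, self.grads)
        g = np.zeros(2 * m.n_nodes)
        np.add.at(g, self.dofs, f_el.reshape(-1, 8))
        K = None
        if with_stiffness:
            k_el = self.wdet * np.einsum("gaJ,egiJkL,gbL->eaibk",
                                         self.grads, Ahat, self.grads,
                                         optimize=True)
            K = sparse.coo_matrix(
                (k_el.reshape(-1, 64).ravel(), (self.rows, self.cols)),
                shape=(2 * m.n_nodes, 2 * m.n_nodes)).tocsr()
        # averages for post-processing
        detF2 = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
        J = detF2 * lam3
        sig = np.einsum("egiJ,egkJ->egik", P, F) / J[..., None, None]
        V0 = m.n_elements * self.n_gp * self.wdet
        mean_pk1 = P.sum(axis=(0, 1)) * self.wdet / V0
        mean_cauchy = ((sig * J[..., None, None]).sum(axis=(0, 1))
                       / J.sum())
        mean_J = J.mean()
        self._post = (mean_pk1, mean_cauchy, mean_J, V0)
        return g, K


def solve_load_case(model: FEModel, materials: dict, case: MacroLoadCase,
                    n_increments: int = 5, newton_tol: float = 1e-11,
                    max_newton_iter: int = 25, max_halvings: int = 3,
                    pbc: PBCConstraints | None = None) -> CaseResult:
    """Incremental Newton-Raphson solve of one macro test.

    The prescribed macro components are ramped over ``n_increments``
    steps with automatic halving (up to ``max_halvings`` levels) on
    divergence.  Free macro components carry zero conjugate force.
    """
    if pbc is None:
        pbc = periodic_couplings(model)
    T_w, T_H = _transform_matrices(model, pbc)
    prescribed = case.prescribed()
    free_idx = [i for i in range(4) if i not in prescribed]
    T_f = T_H[:, free_idx] if free_idx else None
    asm = _Assembler(model, materials)
    n_w = T_w.shape[1]

    w = np.zeros(n_w)
    h_free = np.zeros(len(free_idx))
    history = []

    def u_of(w, h_free, frac):
        H = np.zeros(4)
        for i, v in prescribed.items():
            H[i] = v * frac
        H[free_idx] = h_free
        return T_w @ w + T_H @ H, H

    frac_done = 0.0
    dfrac = 1.0 / n_increments
    halvings = 0
    force_scale = None
    prev_state = None           # (frac, w, h_free) one converged step back
    while frac_done < 1.0 - 1e-12:
        frac_try = min(1.0, frac_done + dfrac)
        # secant predictor: extrapolate the converged fluctuation path
        if prev_state is not None and frac_done > prev_state[0]:
            s = (frac_try - frac_done) / (frac_done - prev_state[0])
            w_it = w + s * (w - prev_state[1])
            h_it = h_free + s * (h_free - prev_state[2])
        else:
            w_it, h_it = w.copy(), h_free.copy()
        lam3_save = asm.lam3.copy()
        ok = False
        def reduced_residual(g):
            R_parts = [T_w.T @ g]
            if T_f is not None:
                R_parts.append(T_f.T @ g)
            return np.concatenate(R_parts)

        try:
            prev_rnorm = np.inf
            for it in range(max_newton_iter):
                u, H = u_of(w_it, h_it, frac_try)
                g, K = asm.response(u)
                R = reduced_residual(g)
                rnorm = float(np.linalg.norm(R))
                history.append((frac_try, it, rnorm))
                if force_scale is None or rnorm > force_scale:
                    force_scale = max(rnorm, 1e-30)
                if rnorm <= newton_tol * force_scale:
                    ok = True
                    break
                # quadratic convergence has bottomed out at the noise
                # floor of the local plane-stress condensation
                if rnorm >= 0.5 * prev_rnorm and rnorm <= 1e-7 * force_scale:
                    ok = True
                    break
                prev_rnorm = rnorm
                cols = [T_w] + ([T_f] if T_f is not None else [])
                T_all = sparse.hstack(cols).tocsr()
                K_red = (T_all.T @ (K @ T_all)).tocsc()
                dz = spsolve(K_red, -R)
                # backtracking line search on the residual norm
                alpha = 1.0
                best = None
                for _ls in range(5):
                    w_try = w_it + alpha * dz[:n_w]
                    h_try = h_it + alpha * dz[n_w:] if T_f is not None \
                        else h_it
                    try:
                        g_try, _ = asm.response(
                            u_of(w_try, h_try, frac_try)[0],
                            with_stiffness=False)
                    except (RuntimeError, ValueError):
                        alpha *= 0.5
                        continue
                    r_try = float(np.linalg.norm(reduced_residual(g_try)))
                    if best is None or r_try < best[2]:
                        best = (w_try, h_try, r_try)
                    if r_try <= (1.0 - 1e-4 * alpha) * rnorm:
                        break
                    alpha *= 0.5
                if best is None:
                    raise RuntimeError("line search found no admissible step")
                w_it, h_it, _ = best
                # displacement update below any physical resolution:
                # the load is so small the relative criterion cannot bite
                if np.abs(dz).max() <= 1e-12 * model.h_um:
                    ok = True
                    break
        except (RuntimeError, ValueError):
            ok = False
        if ok:
            prev_state = (frac_done, w, h_free)
            w, h_free = w_it, h_it
            frac_done = frac_try
            force_scale = None
        else:
            asm.lam3 = lam3_save
            halvings += 1
            if halvings > max_halvings:
                raise NewtonDivergence(
                    f"Newton diverged for {case.kind} sign {case.sign} "
                    f"after {max_halvings} increment halvings", history)
            dfrac /= 2.0

    u, H = u_of(w, h_free, 1.0)
    g, _ = asm.response(u, with_stiffness=False)
    mean_pk1, mean_cauchy, mean_J, V0 = asm._post
    reaction = np.array(T_H.T @ g).reshape(4) / V0
    react_t = np.array([[reaction[0], reaction[2]],
                        [reaction[3], reaction[1]]])
    Fbar = np.eye(2) + np.array([[H[0], H[2]], [H[3], H[1]]])
    # Hill-Mandel: <J sigma> = <P> Fbar^T with <P> = macro reaction / V0
    Jbar_sigma = mean_cauchy * mean_J
    rhs = react_t @ Fbar.T[:2, :2]
    hm = float(np.linalg.norm(Jbar_sigma - rhs) /
               max(np.linalg.norm(Jbar_sigma), 1e-30))
    return CaseResult(case, H, mean_cauchy, mean_pk1, react_t, hm, history,
                      np.asarray(u))


@dataclass
class ApparentModuli:
    """Secant moduli (kPa) from the six +/-5% tests."""

    E11t: float
    E11c: float
    E22t: float
    E22c: float
    G12t: float
    G12c: float

    def as_dict(self):
        return {k: getattr(self, k)
                for k in ("E11t", "E11c", "E22t", "E22c", "G12t", "G12c")}


def standard_cases(magnitude: float = 0.05, transverse: str = "free"):
    """The six macro tests: tension/compression uniaxial 1, 2 and shear."""
    cases = []
    for kind in ("uniaxial-1", "uniaxial-2", "shear-12"):
        for sign in (+1, -1):
            cases.append(MacroLoadCase(kind, sign, magnitude, transverse))
    return cases


def run_all_cases(model: FEModel, materials: dict, magnitude: float = 0.05,
                  transverse: str = "free", **solver_kw):
    """Solve the six standard cases; returns {(kind, sign): CaseResult}."""
    pbc = periodic_couplings(model)
    results = {}
    for case in standard_cases(magnitude, transverse):
        results[(case.kind, case.sign)] = solve_load_case(
            model, materials, case, pbc=pbc, **solver_kw)
    return results


def apparent_moduli(results: dict) -> ApparentModuli:
    """Secant moduli at the full test strain from the six case results."""
    def get(kind, sign):
        key = (kind, sign)
        if key not in results:
            raise ValueError(f"missing load case {key}")
        return results[key]

    def secant(kind, comp, sign):
        r = get(kind, sign)
        eps = r.case.magnitude
        return abs(r.mean_cauchy[comp]) / eps

    return ApparentModuli(
        E11t=secant("uniaxial-1", (0, 0), +1),
        E11c=secant("uniaxial-1", (0, 0), -1),
        E22t=secant("uniaxial-2", (1, 1), +1),
        E22c=secant("uniaxial-2", (1, 1), -1),
        G12t=secant("shear-12", (0, 1), +1),
        G12c=secant("shear-12", (0, 1), -1),
    )


def rve_convergence_study(base: LabelImage, materials: dict,
                          sizes_um, orientation: OrientationMap | None = None,
                          coarsen: int = 1, magnitude: float = 0.05,
                          rel_tol: float = 0.02, **solver_kw):
    """Apparent moduli and area fractions versus window size.

    Centred square windows of the given physical sizes are cut from the
    base image, mirrored into periodic cells, and homogenized.  The
    convergence size is the smallest size beyond which every modulus
    changes by less than ``rel_tol`` between consecutive sizes.
    """
    from .synthetic import area_fractions
    from .rve import mirror_orthotropic

    sizes = list(sizes_um)
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("sizes_um must be strictly increasing")
    rows = []
    for size in sizes:
        n = int(round(size / base.pixel_size_um))
        ny, nx = base.shape
        if n > min(ny, nx):
            raise ValueError(f"window {size} um exceeds the base image")
        i0, j0 = (ny - n) // 2, (nx - n) // 2
        win = LabelImage(base.labels[i0:i0 + n, j0:j0 + n],
                         base.pixel_size_um)
        omap_win = None
        if orientation is not None:
            omap_win = OrientationMap(
                orientation.angle_deg[i0:i0 + n, j0:j0 + n],
                orientation.coherence[i0:i0 + n, j0:j0 + n],
                orientation.window_px, orientation.pixel_size_um)
        rve = mirror_orthotropic(win, omap_win)
        c = coarsen
        while (2 * n) % c:
            c -= 1
        model = mesh_from_labels(rve, coarsen=c)
        row = {"size_um": float(size)}
        try:
            res = run_all_cases(model, materials, magnitude, **solver_kw)
            row.update(apparent_moduli(res).as_dict())
            row["failed"] = False
        except (NewtonDivergence, RuntimeError) as exc:
            row.update({k: np.nan for k in
                        ("E11t", "E11c", "E22t", "E22c", "G12t", "G12c")})
            row["failed"] = True
            row["error"] = str(exc)
        fr = area_fractions(win)
        row.update({"frac_stroma": fr[0], "frac_epithelium": fr[1],
                    "frac_lumen": fr[2]})
        rows.append(row)
    table = pd.DataFrame(rows)

    conv_size = np.nan
    mod_cols = ["E11t", "E11c", "E22t", "E22c", "G12t", "G12c"]
    vals = table[mod_cols].to_numpy()
    rel = np.abs(np.diff(vals, axis=0)) / np.maximum(np.abs(vals[:-1]), 1e-30)
    for i in range(len(sizes) - 1):
        # converged once every later consecutive change stays below tol
        if np.all(rel[i:] < rel_tol):
            conv_size = float(sizes[i])
            break
    table.attrs["convergence_size_um"] = conv_size
    return table
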