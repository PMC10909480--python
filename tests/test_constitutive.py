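import numpy as np
import pytest

from histomech import (
    NeoHookeanParams,
    HGOParams,
    DeformationState,
    d1_from_poisson,
    neo_hookean_energy,
    hgo_energy,
    cauchy_stress,
    pk2_stress,
    material_tangent,
    plane_stress_condense,
)
from histomech.constitutive import (
    energy_batch,
    pk2_batch,
    pk1_and_tangent_batch,
    _params_arrays,
)


def random_states(n, scale=0.08, seed=0):
    """Admissible (F2d, lam3, angle) triples around the reference."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        F = np.eye(2) + scale * rng.standard_normal((2, 2))
        lam3 = 1.0 + scale * rng.standard_normal()
        if np.linalg.det(F) > 0.3 and lam3 > 0.3:
            out.append((F, lam3, rng.uniform(-90.0, 90.0)))
    return out


def fd_pk1(material, F2d, lam3, ang, h=1e-6):
    """Central finite differences of the energy w.r.t. (F2d, lam3)."""
    C10, D1, k1, k2, kap = _params_arrays(material)

    def W(F2, l3):
        return float(energy_batch(F2, l3, ang, C10, D1, k1, k2, kap))

    P = np.zeros((3, 3))
    for i in range(2):
        for j in range(2):
            Fp, Fm = F2d.copy(), F2d.copy()
            Fp[i, j] += h
            Fm[i, j] -= h
            P[i, j] = (W(Fp, lam3) - W(Fm, lam3)) / (2 * h)
    P[2, 2] = (W(F2d, lam3 + h) - W(F2d, lam3 - h)) / (2 * h)
    return P


@pytest.fixture(scope="module")
def materials(nh_params, hgo_params):
    return {"NH": nh_params, "HGO": hgo_params,
            "HGO_dispersed": HGOParams(nh_params, 120.0, 150.0, 0.2)}


class TestEnergies:
    def test_reference_state_zero(self, nh_params, hgo_params):
        ref = DeformationState(np.eye(2), 1.0, 0.0)
        assert neo_hookean_energy(ref, nh_params) == 0.0
        assert hgo_energy(ref, hgo_params) == 0.0

    def test_nh_isochoric_uniaxial_closed_form(self, nh_params):
        lam = 1.07
        st = DeformationState(np.diag([lam, lam**-0.5]), lam**-0.5)
        expect = nh_params.C10 * (lam**2 + 2.0 / lam - 3.0)
        assert neo_hookean_energy(st, nh_params) == pytest.approx(
            expect, rel=1e-12)

    def test_pure_dilation_volumetric_only(self, nh_params):
        lam = 1.1 ** (1.0 / 3.0)  # J = 1.1, no distortion
        st = DeformationState(np.diag([lam, lam]), lam)
        expect = (1.0 / nh_params.D1) * 0.1**2
        assert neo_hookean_energy(st, nh_params) == pytest.approx(
            expect, rel=1e-9)

    def test_hgo_compression_deactivates_to_nh(self, hgo_params):
        # kappa = 0, fibre-direction compression: E < 0, fibre term off
        lam = 0.95
        st = DeformationState(np.diag([lam, lam**-0.5]), lam**-0.5, 0.0)
        e_hgo = hgo_energy(st, hgo_params)
        e_nh = neo_hookean_energy(st, hgo_params.base)
        assert e_hgo == e_nh  # bit-wise

    def test_hgo_tension_fibre_term_closed_form(self, hgo_params):
        lam = 1.05
        st = DeformationState(np.diag([lam, lam**-0.5]), lam**-0.5, 0.0)
        # isochoric: Ibar4 = lam^2 exactly
        E = lam**2 - 1.0
        k1, k2 = hgo_params.k1, hgo_params.k2
        fibre = k1 / (2 * k2) * (np.exp(k2 * E**2) - 1.0)
        expect = neo_hookean_energy(st, hgo_params.base) + fibre
        assert hgo_energy(st, hgo_params) == pytest.approx(expect, rel=1e-12)

    def test_kappa_one_third_angle_independent(self, nh_params):
        iso = HGOParams(nh_params, 100.0, 50.0, 1.0 / 3.0)
        F = np.array([[1.06, 0.02], [0.01, 0.97]])
        vals = [hgo_energy(DeformationState(F, 1.01, a), iso)
                for a in (-80.0, -15.0, 0.0, 42.0)]
        assert np.ptp(vals) < 1e-12 * max(vals)

    def test_kappa_out_of_range_rejected(self, nh_params):
        with pytest.raises(ValueError):
            HGOParams(nh_params, 100.0, 50.0, 0.5)
        with pytest.raises(ValueError):
            HGOParams(nh_params, 100.0, 50.0, -0.01)


class TestStressAndTangent:
    @pytest.mark.parametrize("mat_key", ["NH", "HGO", "HGO_dispersed"])
    def test_stress_matches_energy_fd(self, materials, mat_key):
        mat = materials[mat_key]
        C10, D1, k1, k2, kap = _params_arrays(mat)
        worst = 0.0
        for F, lam3, ang in random_states(40, seed=hash(mat_key) % 2**31):
            P, _ = pk1_and_tangent_batch(F, lam3, ang, C10, D1, k1, k2, kap)
            Pfd = fd_pk1(mat, F, lam3, ang)
            err = np.abs(P - Pfd).max() / max(np.abs(Pfd).max(), 1.0)
            worst = max(worst, err)
        assert worst < 1e-5

    @pytest.mark.parametrize("mat_key", ["NH", "HGO", "HGO_dispersed"])
    def test_tangent_matches_stress_fd(self, materials, mat_key):
        mat = materials[mat_key]
        C10, D1, k1, k2, kap = _params_arrays(mat)
        h = 1e-6
        worst = 0.0
        for F, lam3, ang in random_states(10, seed=1 + hash(mat_key) % 2**31):
            _, A = pk1_and_tangent_batch(F, lam3, ang, C10, D1, k1, k2, kap)
            scale = np.abs(A).max()
            for i in range(2):
                for j in range(2):
                    Fp, Fm = F.copy(), F.copy()
                    Fp[i, j] += h
                    Fm[i, j] -= h
                    Pp, _ = pk1_and_tangent_batch(Fp, lam3, ang,
                                                  C10, D1, k1, k2, kap)
                    Pm, _ = pk1_and_tangent_batch(Fm, lam3, ang,
                                                  C10, D1, k1, k2, kap)
                    err = np.abs(A[:, :, i, j] - (Pp - Pm) / (2 * h)).max()
                    worst = max(worst, err / scale)
        assert worst < 1e-4

    def test_reference_stress_zero(self, materials):
        ref = DeformationState(np.eye(2), 1.0, 0.0)
        for mat in materials.values():
            assert np.allclose(cauchy_stress(ref, mat), 0.0, atol=1e-14)

    def test_small_strain_shear_modulus(self, nh_params):
        # CC at the reference has isotropic form with mu = 2*C10
        ref = DeformationState(np.eye(2), 1.0)
        CC = material_tangent(ref, nh_params)
        mu = CC[0, 1, 0, 1]
        assert mu == pytest.approx(2.0 * nh_params.C10, rel=1e-12)

    def test_frame_indifference(self, hgo_params):
        C10, D1, k1, k2, kap = _params_arrays(hgo_params)
        F = np.array([[1.05, 0.03], [0.0, 0.96]])
        ang = 20.0
        w0 = float(energy_batch(F, 1.02, ang, C10, D1, k1, k2, kap))
        for th in (15.0, 60.0, -45.0):
            t = np.deg2rad(th)
            Q = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
            # in-plane rotation applied to F; the fibre vector is
            # material (referential), so it is NOT co-rotated
            w = float(energy_batch(Q @ F, 1.02, ang, C10, D1, k1, k2, kap))
            assert w == pytest.approx(w0, abs=1e-10 * max(1.0, w0))

    def test_hgo_inactive_tangent_equals_nh(self, hgo_params):
        lam = 0.95
        st = DeformationState(np.diag([lam, lam**-0.5]), lam**-0.5, 0.0)
        assert np.array_equal(material_tangent(st, hgo_params),
                              material_tangent(st, hgo_params.base))
        assert np.array_equal(pk2_stress(st, hgo_params),
                              pk2_stress(st, hgo_params.base))

    def test_convexity_near_reference(self, materials):
        # tangent at F = I is positive definite on symmetric in-plane
        # strain directions
        ref = DeformationState(np.eye(2), 1.0, 0.0)
        for mat in materials.values():
            _, A = pk1_and_tangent_batch(
                np.eye(2), 1.0, 0.0, *_params_arrays(mat))
            M = A[:2, :2, :2, :2].reshape(4, 4)
            sym = np.array([[1, 0, 0, 0], [0, 0, 0, 1],
                            [0, 1, 1, 0]]) / np.sqrt(2)
            eigs = np.linalg.eigvalsh(sym @ M @ sym.T)
            assert np.all(eigs > 0)


class TestPlaneStress:
    def test_identity(self, nh_params):
        lam3, sig, Ahat = plane_stress_condense(np.eye(2), nh_params)
        assert lam3 == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(sig, 0.0, atol=1e-12)
        assert Ahat.shape == (2, 2, 2, 2)

    def test_incompressible_equibiaxial_lambda3(self):
        nh = NeoHookeanParams.from_poisson(10.0, 0.4999)
        lam = 1.06
        lam3, _, _ = plane_stress_condense(np.diag([lam, lam]), nh)
        assert lam3 == pytest.approx(lam**-2, rel=1e-3)

    def test_incompressible_uniaxial_stress_closed_form(self):
        nh = NeoHookeanParams.from_poisson(10.0, 0.4999)
        lam = 1.05
        lam3, sig, _ = plane_stress_condense(
            np.diag([lam, lam**-0.5]), nh)
        expect = 2.0 * nh.C10 * (lam**2 - 1.0 / lam)
        assert sig[0, 0] == pytest.approx(expect, rel=2e-3)

    def test_sigma33_residual_below_tolerance(self, hgo_params):
        from histomech.constitutive import solve_plane_stress_lambda3, \
            pk2_batch
        C10, D1, k1, k2, kap = _params_arrays(hgo_params)
        for F, _, ang in random_states(20, seed=7):
            lam3 = solve_plane_stress_lambda3(F, ang, C10, D1, k1, k2, kap)
            S = pk2_batch(F, lam3, ang, C10, D1, k1, k2, kap)
            sig33 = float(lam3 * (lam3 * S[2, 2]) /
                          (np.linalg.det(F) * lam3))
            assert abs(sig33) < 1e-6 * max(1.0, np.abs(S).max())

    def test_non_positive_det_rejected(self, nh_params):
        with pytest.raises(ValueError):
            plane_stress_condense(np.diag([1.0, -0.5]), nh_params)


def test_d1_from_poisson_identities():
    # K0/mu0 ratio must reproduce the requested Poisson ratio
    C10, nu = 8.0, 0.47
    D1 = d1_from_poisson(C10, nu)
    mu0, K0 = 2.0 * C10, 2.0 / D1
    nu_back = (3 * K0 - 2 * mu0) / (2 * (3 * K0 + mu0))
    assert nu_back == pytest.approx(nu, rel=1e-12)
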