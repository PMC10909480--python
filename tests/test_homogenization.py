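import numpy as np
import pytest

from histomech import (
    LabelImage,
    OrientationMap,
    NeoHookeanParams,
    HGOParams,
    PeriodicRVE,
    mesh_from_labels,
    periodic_couplings,
    solve_load_case,
    run_all_cases,
    apparent_moduli,
    rve_convergence_study,
    MacroLoadCase,
    MicrostructureSpec,
    generate_microstructure,
    generate_fiber_field,
    mirror_orthotropic,
    STROMA,
    EPITHELIUM,
    LUMEN,
)
from histomech.homogenization import PBCConstraints
from pointwise_oracle import pointwise_apparent


def homogeneous_model(n=8, px=10.0, angle=0.0):
    model = mesh_from_labels(LabelImage(np.zeros((n, n), dtype=np.uint8),
                                        px))
    model.angles_deg[:] = angle
    return model


@pytest.fixture(scope="module")
def het_rve():
    """Small heterogeneous mirrored RVE with a fibre map (32x32 elements)."""
    spec = MicrostructureSpec(
        width_px=16, height_px=16, pixel_size_um=32.0, n_acini=2,
        lumen_radius_mean_um=55.0, lumen_radius_sd_um=8.0,
        epithelium_thickness_um=40.0, elongation=1.2,
        preferred_angle_deg=10.0, angle_dispersion_deg=0.0,
        min_gap_um=64.0, seed=1)
    image, _ = generate_microstructure(spec)
    omap = generate_fiber_field(image, mode="channel_tangent")
    return mirror_orthotropic(image, omap)


class TestMesh:
    def test_structured_counts(self):
        model = mesh_from_labels(LabelImage(np.zeros((2, 2),
                                            dtype=np.uint8), 1.0))
        assert model.n_elements == 4
        assert model.n_nodes == 9
        # CCW connectivity of the first element
        assert list(model.elements[0]) == [0, 1, 4, 3]

    def test_majority_vote_with_priority_ties(self):
        raster = np.array([[0, 1, 1, 1],
                           [1, 0, 1, 1],
                           [2, 2, 0, 0],
                           [2, 2, 0, 2]], dtype=np.uint8)
        model = mesh_from_labels(LabelImage(raster, 1.0), coarsen=2)
        # blocks row-major from the bottom row: 2-2 stroma/epithelium tie
        # breaks to stroma; pure epithelium; pure lumen; 2-1-1 stroma
        assert model.labels.tolist() == [STROMA, EPITHELIUM, LUMEN, STROMA]

    def test_constant_orientation_carried(self, all_stroma):
        ang = np.full(all_stroma.shape, 30.0)
        omap = OrientationMap(ang, np.ones_like(ang), 1,
                              all_stroma.pixel_size_um)
        model = mesh_from_labels(PeriodicRVE(all_stroma, omap), coarsen=2)
        assert np.all(model.angles_deg == 30.0)

    def test_non_divisor_coarsen_rejected(self, all_stroma):
        with pytest.raises(ValueError):
            mesh_from_labels(all_stroma, coarsen=5)


class TestPeriodicCouplings:
    def test_constraint_count_small_mesh(self):
        # 2x2 elements: 8 boundary nodes; 1 + 1 interior edge pairs and
        # 3 corner identifications = 5 pairings, enumerated by hand
        model = mesh_from_labels(LabelImage(np.zeros((2, 2),
                                            dtype=np.uint8), 1.0))
        pbc = periodic_couplings(model)
        assert len(pbc.pairs) == 5
        assert len(pbc.pairs) == 2 * (2 - 1) + 3

    def test_every_boundary_slave_once(self):
        model = homogeneous_model(n=4)
        pbc = periodic_couplings(model)
        slaves = [s for s, _ in pbc.pairs]
        assert len(slaves) == len(set(slaves))
        assert len(pbc.pairs) == 2 * (4 - 1) + 3

    def test_redundant_constraint_rejected(self):
        model = homogeneous_model(n=2)
        pbc = periodic_couplings(model)
        with pytest.raises(ValueError, match="redundant"):
            PBCConstraints(pbc.pairs + [pbc.pairs[0]], pbc.master_corner)

    def test_homogeneous_field_is_affine(self, nh_params):
        # homogeneity: the affine field u = H.X solves equilibrium
        # exactly, so the periodic fluctuation vanishes
        model = homogeneous_model(n=4)
        mats = {STROMA: nh_params}
        case = MacroLoadCase("uniaxial-1", +1, 0.05, transverse="fixed")
        res = solve_load_case(model, mats, case)
        Ht = np.array([[res.H[0], res.H[2]], [res.H[3], res.H[1]]])
        affine = model.nodes @ Ht.T
        assert np.abs(res.u.reshape(-1, 2) - affine).max() < 1e-10


class TestHomogeneousExactness:
    @pytest.mark.parametrize("mat_kind", ["NH", "HGO"])
    @pytest.mark.parametrize("kind,sign", [
        ("uniaxial-1", +1), ("uniaxial-1", -1),
        ("uniaxial-2", +1), ("uniaxial-2", -1),
        ("shear-12", +1), ("shear-12", -1)])
    def test_matches_pointwise_response(self, nh_params, hgo_params,
                                        mat_kind, kind, sign):
        mat = nh_params if mat_kind == "NH" else hgo_params
        model = homogeneous_model(n=4, angle=0.0)
        res = solve_load_case(model, {STROMA: mat},
                              MacroLoadCase(kind, sign, 0.05))
        comp = {"uniaxial-1": (0, 0), "uniaxial-2": (1, 1),
                "shear-12": (0, 1)}[kind]
        fe = abs(res.mean_cauchy[comp]) / 0.05
        oracle = pointwise_apparent(mat, 0.0, kind, sign * 0.05)
        assert fe == pytest.approx(oracle, rel=5e-3)
        assert res.hill_mandel_rel < 1e-8

    def test_tiny_load_gives_tiny_stress(self, nh_params):
        model = homogeneous_model(n=2)
        res = solve_load_case(model, {STROMA: nh_params},
                              MacroLoadCase("uniaxial-1", +1, 1e-10))
        assert np.abs(res.mean_cauchy).max() < 1e-7


class TestPhysicalInvariants:
    def test_fibre_rotation_swaps_directions(self, hgo_params, nh_params):
        mats = {STROMA: hgo_params}
        m0 = homogeneous_model(n=4, angle=0.0)
        m90 = homogeneous_model(n=4, angle=-90.0)
        mod0 = apparent_moduli(run_all_cases(m0, mats))
        mod90 = apparent_moduli(run_all_cases(m90, mats))
        assert mod90.E11t == pytest.approx(mod0.E22t, rel=1e-2)
        assert mod90.E22t == pytest.approx(mod0.E11t, rel=1e-2)
        assert mod90.E11c == pytest.approx(mod0.E22c, rel=1e-2)

    def test_kappa_third_isotropic_moduli(self, nh_params):
        iso = HGOParams(NeoHookeanParams.from_poisson(17.5, 0.49),
                        155.0, 200.0, 1.0 / 3.0)
        model = homogeneous_model(n=4, angle=37.0)
        mod = apparent_moduli(run_all_cases(model, {STROMA: iso}))
        assert mod.E11t == pytest.approx(mod.E22t, rel=5e-3)
        assert mod.E11c == pytest.approx(mod.E22c, rel=5e-3)

    def test_compressive_moduli_k1_independent(self, nh_params):
        base = NeoHookeanParams.from_poisson(17.5, 0.49)
        model = homogeneous_model(n=4, angle=0.0)
        case = MacroLoadCase("uniaxial-1", -1, 0.05)
        sig = []
        for k1 in (10.0, 155.0, 300.0):
            res = solve_load_case(model,
                                  {STROMA: HGOParams(base, k1, 200.0, 0.0)},
                                  case)
            sig.append(res.mean_cauchy[0, 0])
        assert sig[0] == sig[1] == sig[2]  # bit-identical

    def test_tension_stiffer_than_compression_along_fibres(self,
                                                           hgo_params):
        model = homogeneous_model(n=4, angle=0.0)
        mod = apparent_moduli(run_all_cases(model, {STROMA: hgo_params}))
        assert mod.E11t > mod.E11c

    def test_small_strain_linear_limit(self):
        nh = NeoHookeanParams.from_poisson(10.0, 0.4995)
        model = homogeneous_model(n=2)
        mats = {STROMA: nh}
        mod = apparent_moduli(run_all_cases(model, mats, magnitude=0.005))
        # nu -> 0.5: E -> 6 C10, G -> mu = 2 C10
        assert mod.E11t == pytest.approx(60.0, rel=0.02)
        assert mod.E11c == pytest.approx(60.0, rel=0.02)
        assert mod.G12t == pytest.approx(20.0, rel=0.02)


class TestHeterogeneous:
    def test_hill_mandel_on_microstructure(self, het_rve, nh_params,
                                           hgo_params):
        model = mesh_from_labels(het_rve)
        mats = {STROMA: hgo_params, EPITHELIUM: nh_params,
                LUMEN: nh_params}
        res = solve_load_case(model, mats, MacroLoadCase("uniaxial-1", +1))
        assert res.hill_mandel_rel < 1e-8
        assert res.mean_cauchy[0, 0] > 0

    def test_moduli_monotone_in_stromal_stiffness(self, het_rve, nh_params):
        model = mesh_from_labels(het_rve)
        prev = None
        for C10 in (5.0, 17.5, 30.0):
            mats = {STROMA: HGOParams(
                NeoHookeanParams.from_poisson(C10, 0.49), 155.0, 200.0),
                EPITHELIUM: nh_params, LUMEN: nh_params}
            res = solve_load_case(model, mats,
                                  MacroLoadCase("uniaxial-1", -1))
            val = abs(res.mean_cauchy[0, 0])
            if prev is not None:
                assert val > prev
            prev = val

    def test_missing_material_rejected(self, het_rve):
        model = mesh_from_labels(het_rve)
        with pytest.raises(ValueError, match="label"):
            solve_load_case(model,
                            {STROMA: NeoHookeanParams.from_poisson(10.0)},
                            MacroLoadCase("shear-12", +1))


class TestApparentModuli:
    def test_secant_arithmetic(self, nh_params):
        model = homogeneous_model(n=2)
        results = run_all_cases(model, {STROMA: nh_params})
        mod = apparent_moduli(results)
        r = results[("uniaxial-1", +1)]
        assert mod.E11t == abs(r.mean_cauchy[0, 0]) / 0.05

    def test_missing_case_rejected(self, nh_params):
        model = homogeneous_model(n=2)
        results = run_all_cases(model, {STROMA: nh_params})
        del results[("shear-12", -1)]
        with pytest.raises(ValueError, match="missing"):
            apparent_moduli(results)


class TestConvergenceStudy:
    def test_homogeneous_converges_at_smallest(self, nh_params):
        base = LabelImage(np.zeros((16, 16), dtype=np.uint8), 10.0)
        mats = {STROMA: nh_params, EPITHELIUM: nh_params, LUMEN: nh_params}
        table = rve_convergence_study(base, mats, [40.0, 80.0, 160.0])
        assert len(table) == 3
        assert table.attrs["convergence_size_um"] == 40.0
        assert np.allclose(table["E11t"], table["E11t"].iloc[0], rtol=1e-6)

    def test_sizes_must_increase(self, nh_params, all_stroma):
        with pytest.raises(ValueError):
            rve_convergence_study(all_stroma, {STROMA: nh_params},
                                  [100.0, 50.0])
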