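import numpy as np
import pytest

from oculomech.constitutive import CORNEA_PARAMS, SCLERA_PARAMS, MaterialParams
from oculomech.geometry import build_eye_mesh, build_uniform_sphere
from oculomech.pressurize import (MMHG_TO_MPA, FieldResult, PressureLoad,
                                  SolverConfig, _MembraneModel,
                                  low_stress_area_fraction, mmhg_to_mpa,
                                  peak_in_central_area, regional_summary,
                                  solve_pressurized, solve_ramp)

# compliant near-linear material for the analytic shell oracles
NEAR_LINEAR = MaterialParams(alpha=2.0, mu=10.0, beta=1.0, g_visc=0.0)


def sphere_materials(params=NEAR_LINEAR):
    return {"posterior_sclera": params}


class TestUnitConversion:
    def test_zero(self):
        assert mmhg_to_mpa(0.0) == 0.0

    def test_defined_constant(self):
        assert mmhg_to_mpa(10.0) == pytest.approx(1.33322e-3, rel=1e-12)

    def test_linearity(self):
        assert mmhg_to_mpa(100.0) == pytest.approx(10 * mmhg_to_mpa(10.0), rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mmhg_to_mpa(-1.0)
        with pytest.raises(ValueError):
            PressureLoad(-5.0)


class TestSolver:
    def test_zero_load_identity(self):
        mesh = build_uniform_sphere(15.0, 1.0, level=2)
        res = solve_pressurized(mesh, sphere_materials(), PressureLoad(0.0))
        assert np.allclose(res.displacement, 0.0)
        assert np.allclose(res.eq_stress, 0.0)
        assert np.allclose(res.eq_strain, 0.0)

    def test_missing_material_rejected(self):
        mesh = build_uniform_sphere(15.0, 1.0, level=2)
        with pytest.raises(KeyError, match="posterior_sclera"):
            solve_pressurized(mesh, {"cornea": NEAR_LINEAR}, PressureLoad(10.0))

    @pytest.mark.parametrize("radius,thickness", [(15.0, 1.0), (10.0, 0.5)])
    def test_laplace_law(self, radius, thickness):
        # thin-walled sphere oracle: sigma = p R / (2 t), within 5 %
        mesh = build_uniform_sphere(radius, thickness, level=3)
        res = solve_pressurized(mesh, sphere_materials(), PressureLoad(30.0))
        p = mmhg_to_mpa(30.0)
        expected = p * radius / (2.0 * thickness)
        mean_stress = np.average(res.eq_stress, weights=mesh.face_areas())
        assert abs(mean_stress - expected) / expected < 0.05

    def test_small_load_linearity(self):
        # doubling a small load doubles stresses within 2 %; the tiny loads
        # sit at the float64 energy-difference floor, so no strict residual
        cfg = SolverConfig(strict=False)
        mesh = build_uniform_sphere(15.0, 1.0, level=2)
        r1 = solve_pressurized(mesh, sphere_materials(), PressureLoad(1.0), cfg)
        r2 = solve_pressurized(mesh, sphere_materials(), PressureLoad(2.0), cfg)
        ratio = r2.eq_stress.mean() / r1.eq_stress.mean()
        assert ratio == pytest.approx(2.0, rel=0.02)

    def test_residual_below_tolerance(self):
        mesh = build_uniform_sphere(15.0, 1.0, level=2)
        res = solve_pressurized(mesh, sphere_materials(), PressureLoad(30.0))
        assert res.diagnostics["residual_norm"] <= res.diagnostics["tol"]

    def test_global_equilibrium_of_pressure_resultant(self):
        # net follower-pressure force on a closed surface vanishes
        mesh = build_uniform_sphere(15.0, 1.0, level=2)
        model = _MembraneModel(mesh, sphere_materials())
        res = solve_pressurized(mesh, sphere_materials(), PressureLoad(30.0))
        x = (mesh.points + res.displacement)
        tri = x[mesh.faces]
        normals = 0.5 * np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        p = mmhg_to_mpa(30.0)
        net = p * normals.sum(axis=0)
        per_face = p * np.linalg.norm(normals, axis=1).sum()
        assert np.linalg.norm(net) < 1e-9 * per_face

    def test_stress_nonnegative(self):
        mesh = build_uniform_sphere(15.0, 1.0, level=2)
        res = solve_pressurized(mesh, sphere_materials(), PressureLoad(60.0))
        assert np.all(res.eq_stress >= 0.0)

    def test_mesh_convergence(self):
        # one refinement changes the globe-mean equivalent stress by < 3 %
        means = []
        for level in (3, 4):
            mesh = build_uniform_sphere(15.0, 1.0, level=level)
            res = solve_pressurized(mesh, sphere_materials(), PressureLoad(30.0))
            means.append(np.average(res.eq_stress, weights=mesh.face_areas()))
        assert abs(means[1] - means[0]) / means[1] < 0.03

    def test_equibiaxial_stress_matches_material_law(self):
        # on the uniform sphere the state is equibiaxial: solve for the
        # stretch from the material law + Laplace balance and compare
        mesh = build_uniform_sphere(15.0, 1.0, level=3)
        res = solve_pressurized(mesh, sphere_materials(), PressureLoad(30.0))
        s1, s2 = res.principal_stress.T
        # per-facet anisotropy is bounded by the icosphere's facet
        # distortion; the area means must agree tightly
        assert np.all(s1 / s2 < 1.15)
        w = mesh.face_areas()
        assert np.average(s1, weights=w) == pytest.approx(
            np.average(s2, weights=w), rel=0.02)

    def test_ramp_mode_smoke(self):
        mesh = build_uniform_sphere(15.0, 1.0, level=2)
        mat = MaterialParams(alpha=2.0, mu=10.0, beta=0.5, g_visc=5.0)
        res = solve_ramp(mesh, {"posterior_sclera": mat}, PressureLoad(30.0),
                         duration=2.0, n_steps=5)
        assert np.all(np.isfinite(res.eq_stress))
        assert res.diagnostics["transient"] is True

    def test_ramp_converges_to_static_for_long_times(self):
        mesh = build_uniform_sphere(15.0, 1.0, level=2)
        mat = MaterialParams(alpha=2.0, mu=10.0, beta=2.0, g_visc=1.0)
        mats = {"posterior_sclera": mat}
        static = solve_pressurized(mesh, mats, PressureLoad(30.0))
        slow = solve_ramp(mesh, mats, PressureLoad(30.0), duration=50.0, n_steps=25)
        assert np.allclose(slow.eq_stress.mean(), static.eq_stress.mean(), rtol=0.02)


class TestRegionalSummary:
    def _fake_result(self, mesh, stress):
        n = mesh.n_faces
        return FieldResult(displacement=np.zeros_like(mesh.points),
                           principal_stress=np.stack([stress, stress], axis=1),
                           eq_stress=stress, eq_strain=stress / 10.0,
                           region=mesh.region.copy(), diagnostics={})

    def test_all_zero_field(self):
        mesh = build_eye_mesh()
        res = self._fake_result(mesh, np.zeros(mesh.n_faces))
        table = regional_summary(mesh, res)
        assert (table[["stress_min_mpa", "stress_mean_mpa", "stress_max_mpa"]]
                .to_numpy() == 0).all()

    def test_uniform_field(self):
        mesh = build_eye_mesh()
        res = self._fake_result(mesh, np.ones(mesh.n_faces))
        table = regional_summary(mesh, res, stress_threshold=0.5)
        assert np.allclose(table["stress_mean_mpa"], 1.0)
        assert np.allclose(table["area_frac_above_threshold"], 1.0)

    def test_region_areas_sum_to_total(self):
        mesh = build_eye_mesh()
        res = self._fake_result(mesh, np.zeros(mesh.n_faces))
        table = regional_summary(mesh, res)
        assert table["area_mm2"].sum() == pytest.approx(
            mesh.face_areas().sum(), rel=1e-9)


class TestCentralPeakHelpers:
    def test_peak_in_central_area_basic(self):
        key = np.array([0.1, 0.2, 0.9, 1.0])
        areas = np.ones(4)
        central_peak = np.array([0.0, 5.0, 1.0, 1.0])
        edge_peak = np.array([0.0, 1.0, 1.0, 5.0])
        assert peak_in_central_area(key, areas, central_peak, frac=0.5)
        assert not peak_in_central_area(key, areas, edge_peak, frac=0.5)

    def test_low_stress_fraction_bounds(self):
        mesh = build_eye_mesh()
        rng = np.random.default_rng(0)
        stress = rng.uniform(0.0, 1.0, mesh.n_faces)
        res = FieldResult(displacement=np.zeros_like(mesh.points),
                          principal_stress=np.stack([stress, stress], axis=1),
                          eq_stress=stress, eq_strain=stress,
                          region=mesh.region.copy(), diagnostics={})
        frac = low_stress_area_fraction(mesh, res)
        assert 0.0 <= frac <= 1.0
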