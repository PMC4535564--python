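"""Constitutive-law tests.

Independent oracles used here:
* arbitrary-precision (mpmath) direct evaluation of the energy/stress formulas,
* the analytic constant-rate solution ``(G r / beta) (1 - exp(-beta t))`` of
  the hereditary integral,
* the analytic impulse response ``G eps0 exp(-beta t)``,
* direct trapezoidal quadrature of the convolution on the same grid.
"""

import mpmath
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oculomech.constitutive import (DeformationHistory, MaterialParams,
                                    ogden_energy, ogden_uniaxial_stress,
                                    total_uniaxial_stress, visco_stress)

mpmath.mp.dps = 50


def mp_energy(alpha, mu, lam):
    a, m, l = map(mpmath.mpf, (alpha, mu, lam))
    return float((m / a) * (l ** a + 2 * l ** (-a / 2) - 3))


def mp_stress(alpha, mu, lam):
    a, m, l = map(mpmath.mpf, (alpha, mu, lam))
    return float(m * (l ** a - l ** (-a / 2)))


params_strategy = st.builds(
    MaterialParams,
    alpha=st.floats(0.5, 50.0),
    mu=st.floats(0.01, 10.0),
    beta=st.floats(0.01, 10.0),
    g_visc=st.floats(0.0, 10.0),
)


class TestMaterialParams:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            MaterialParams(alpha=0.0, mu=1.0, beta=1.0, g_visc=0.0)
        with pytest.raises(ValueError):
            MaterialParams(alpha=2.0, mu=-1.0, beta=1.0, g_visc=0.0)
        with pytest.raises(ValueError):
            MaterialParams(alpha=2.0, mu=1.0, beta=0.0, g_visc=0.0)
        with pytest.raises(ValueError):
            MaterialParams(alpha=2.0, mu=1.0, beta=1.0, g_visc=-0.1)

    def test_single_term_default(self, sclera):
        assert sclera.n_terms == 1

    def test_multi_term(self):
        p = MaterialParams(alpha=(2.0, 4.0), mu=(1.0, 0.5), beta=1.0, g_visc=0.0)
        assert p.n_terms == 2
        # two-term energy is the sum of the single-term energies
        w = ogden_energy(p, 1.3)
        w1 = ogden_energy(MaterialParams(2.0, 1.0, 1.0, 0.0), 1.3)
        w2 = ogden_energy(MaterialParams(4.0, 0.5, 1.0, 0.0), 1.3)
        assert w == pytest.approx(w1 + w2, rel=1e-12)


class TestOgdenEnergy:
    def test_reference_state_zero(self, sclera, cornea, simple_params):
        for p in (sclera, cornea, simple_params):
            assert ogden_energy(p, 1.0) == pytest.approx(0.0, abs=1e-14)

    def test_hand_computed(self, simple_params):
        # (1/2)(4 + 2*(1/2) - 3) = 1.0 MPa
        assert ogden_energy(simple_params, 2.0) == pytest.approx(1.0, rel=1e-12)

    def test_against_high_precision(self, sclera):
        expected = mp_energy(27.7, 0.774, 1.02)
        assert ogden_energy(sclera, 1.02) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_stretch_rejected(self, sclera):
        with pytest.raises(ValueError):
            ogden_energy(sclera, 0.0)
        with pytest.raises(ValueError):
            ogden_energy(sclera, -1.0)

    @given(params=params_strategy, lam=st.floats(0.5, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_nonnegative_zero_only_at_reference(self, params, lam):
        w = ogden_energy(params, lam)
        assert w >= -1e-12
        if abs(lam - 1.0) > 1e-3:
            assert w > 0.0


class TestOgdenStress:
    def test_reference_state_zero(self, sclera):
        assert ogden_uniaxial_stress(sclera, 1.0) == pytest.approx(0.0, abs=1e-14)

    def test_hand_computed(self, simple_params):
        # 2^2 - 2^-1 = 3.5 MPa
        assert ogden_uniaxial_stress(simple_params, 2.0) == pytest.approx(3.5, rel=1e-12)

    def test_against_high_precision(self, sclera):
        expected = mp_stress(27.7, 0.774, 1.02)
        assert expected == pytest.approx(0.751, rel=2e-3)  # printed-value check
        assert ogden_uniaxial_stress(sclera, 1.02) == pytest.approx(expected, rel=1e-12)

    def test_tension_sign(self, sclera):
        assert ogden_uniaxial_stress(sclera, 1.05) > 0.0
        assert ogden_uniaxial_stress(sclera, 0.97) < 0.0

    def test_nonpositive_stretch_rejected(self, sclera):
        with pytest.raises(ValueError):
            ogden_uniaxial_stress(sclera, 0.0)

    @given(params=params_strategy)
    @settings(max_examples=50, deadline=None)
    def test_stress_free_reference_random_params(self, params):
        assert ogden_uniaxial_stress(params, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_energy_derivative_matches_stress(self, sclera):
        # uniaxial incompressible reduction: sigma = lam * dW/dlam
        h = 1e-7
        for lam in (1.01, 1.05, 1.10):
            dw = (ogden_energy(sclera, lam + h) - ogden_energy(sclera, lam - h)) / (2 * h)
            assert lam * dw == pytest.approx(
                ogden_uniaxial_stress(sclera, lam), rel=1e-5)


class TestDeformationHistory:
    def test_validation(self):
        with pytest.raises(ValueError):
            DeformationHistory(time=[0.0], stretch=[1.0])
        with pytest.raises(ValueError):
            DeformationHistory(time=[0.0, 1.0, 0.5], stretch=[1.0, 1.1, 1.2])
        with pytest.raises(ValueError):
            DeformationHistory(time=[0.0, 1.0], stretch=[1.1, 1.2])
        with pytest.raises(ValueError):
            DeformationHistory(time=[0.0, 1.0], stretch=[1.0, 1.1],
                               strain_convention="bogus")

    def test_strain_conventions(self):
        h_eng = DeformationHistory(time=[0.0, 1.0], stretch=[1.0, 1.2])
        h_log = DeformationHistory(time=[0.0, 1.0], stretch=[1.0, 1.2],
                                   strain_convention="logarithmic")
        assert h_eng.strain[-1] == pytest.approx(0.2)
        assert h_log.strain[-1] == pytest.approx(np.log(1.2))


class TestViscoStress:
    def test_constant_stretch_is_zero(self, sclera):
        h = DeformationHistory(time=np.linspace(0, 10, 100), stretch=np.ones(100))
        assert np.allclose(visco_stress(sclera, h), 0.0)

    def test_starts_at_zero(self, sclera, ramp_history):
        assert visco_stress(sclera, ramp_history)[0] == 0.0

    def test_constant_rate_closed_form(self, sclera, ramp_history):
        # oracle: sigma_v(t) = (G r / beta)(1 - exp(-beta t)), r = 0.01/s
        g, beta, r = 1.8, 0.93, 0.01
        t = ramp_history.time
        expected = (g * r / beta) * (1.0 - np.exp(-beta * t))
        got = visco_stress(sclera, ramp_history)
        assert np.allclose(got, expected, atol=2e-6)
        # plateau value G r / beta
        assert got[-1] == pytest.approx(0.019355, rel=1e-3)

    def test_closed_form_second_order_in_dt(self, sclera):
        # midpoint update: error should fall ~4x when dt halves
        g, beta, r = 1.8, 0.93, 0.01
        errs = []
        for n in (51, 101, 201):
            t = np.linspace(0, 5.0, n)
            h = DeformationHistory(time=t, stretch=1.0 + r * t)
            expected = (g * r / beta) * (1.0 - np.exp(-beta * t))
            errs.append(np.max(np.abs(visco_stress(sclera, h) - expected)))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.2)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.2)

    def test_impulse_response(self, sclera):
        # strain step eps0 over one tiny step: sigma_v ~ G eps0 exp(-beta t)
        eps0 = 0.01
        t = np.concatenate(([0.0, 1e-9], np.linspace(1e-3, 3.0, 200)))
        lam = np.concatenate(([1.0], np.full(201, 1.0 + eps0)))
        h = DeformationHistory(time=t, stretch=lam)
        got = visco_stress(sclera, h)
        expected = 1.8 * eps0 * np.exp(-0.93 * t[2:])
        assert np.allclose(got[2:], expected, rtol=1e-5)

    def test_matches_trapezoid_quadrature(self, sclera):
        # independent oracle: direct trapezoidal quadrature of the hereditary
        # integral on the same grid (integrand evaluated per output sample)
        rng = np.random.default_rng(42)
        t = np.linspace(0.0, 4.0, 400)
        lam = 1.0 + 0.05 * t / 4.0 + 0.005 * np.sin(3.0 * t)
        lam[0] = 1.0
        h = DeformationHistory(time=t, stretch=lam)
        got = visco_stress(sclera, h)
        g, beta = 1.8, 0.93
        eps = h.strain
        deps_dt = np.gradient(eps, t)
        oracle = np.zeros_like(t)
        for k in range(1, len(t)):
            kernel = g * np.exp(-beta * (t[k] - t[: k + 1]))
            oracle[k] = np.trapezoid(kernel * deps_dt[: k + 1], t[: k + 1])
        # both are O(dt^2) discretizations of the same integral
        assert np.allclose(got[1:], oracle[1:], rtol=5e-3, atol=1e-7)

    def test_recursion_equals_quadrature_of_increments(self, sclera):
        # tighter oracle: exact evaluation of the midpoint-increment sum,
        # computed directly (no recursion); relative agreement < 1e-8
        t = np.linspace(0.0, 2.0, 300)
        lam = 1.0 + 0.04 * t / 2.0
        h = DeformationHistory(time=t, stretch=lam)
        got = visco_stress(sclera, h)
        g, beta = 1.8, 0.93
        eps = h.strain
        direct = np.zeros_like(t)
        for k in range(1, len(t)):
            tm = 0.5 * (t[1: k + 1] + t[: k])  # midpoints
            direct[k] = np.sum(g * np.diff(eps[: k + 1]) * np.exp(-beta * (t[k] - tm)))
        assert np.allclose(got[1:], direct[1:], rtol=1e-8)

    def test_nonuniform_grid_loop_path(self, sclera):
        t = np.concatenate(([0.0], np.cumsum(np.linspace(0.01, 0.1, 50))))
        lam = 1.0 + 0.001 * t
        h = DeformationHistory(time=t, stretch=lam)
        got = visco_stress(sclera, h)
        # compare against the closed form for the constant rate 0.001/s
        expected = (1.8 * 0.001 / 0.93) * (1.0 - np.exp(-0.93 * t))
        assert np.allclose(got, expected, rtol=5e-3, atol=1e-9)


class TestTotalStress:
    def test_reduces_to_hyperelastic_when_g_zero(self, ramp_history):
        p = MaterialParams(alpha=27.7, mu=0.774, beta=0.93, g_visc=0.0)
        total = total_uniaxial_stress(p, ramp_history)
        hyper = ogden_uniaxial_stress(p, ramp_history.stretch)
        assert np.array_equal(total, hyper)

    def test_zero_for_unit_stretch(self, sclera):
        h = DeformationHistory(time=np.linspace(0, 1, 50), stretch=np.ones(50))
        assert np.allclose(total_uniaxial_stress(sclera, h), 0.0)

    def test_rate_stiffening(self, sclera):
        # same final stretch, rates differing 1000x: faster is stiffer
        lam_max = 1.05
        histories = []
        for duration in (100.0, 0.1):
            t = np.linspace(0.0, duration, 500)
            histories.append(DeformationHistory(
                time=t, stretch=1.0 + (lam_max - 1.0) * t / duration))
        slow, fast = (total_uniaxial_stress(sclera, h) for h in histories)
        assert fast[-1] > slow[-1]
        assert np.all(fast[1:] >= slow[1:] - 1e-12)

    def test_quasi_static_limit(self, sclera):
        # as the rate -> 0 at fixed final stretch, total -> Ogden curve
        lam_max = 1.05
        gaps = []
        for duration in (10.0, 100.0, 1000.0):
            t = np.linspace(0.0, duration, 1000)
            h = DeformationHistory(time=t, stretch=1.0 + (lam_max - 1.0) * t / duration)
            total = total_uniaxial_stress(sclera, h)
            hyper = ogden_uniaxial_stress(sclera, h.stretch)
            gaps.append(np.max(np.abs(total - hyper)))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 1e-4
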