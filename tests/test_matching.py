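import math
from dataclasses import replace

import numpy as np
import pytest

from pcls_oxygen import SurfaceOxygen, TransportParams, default_parameters
from pcls_oxygen.inner import baseline_profile, find_inner_eigenvalues
from pcls_oxygen.matching import (
    MatchingSystem,
    assemble_system,
    overlap_integral,
    overlap_integral_quad,
    projection_load,
    projection_load_quad,
    solve_coefficients,
    solve_oxygen_field,
)
from pcls_oxygen.outer import outer_modes

from oracles import mp_i0, mp_i1, mp_radial_factor, mp_radial_factor_derivative


@pytest.fixture(scope="module")
def assembled7(default_5mm, surface_atm):
    system, transport = default_5mm
    inner = find_inner_eigenvalues(transport, system, 7)
    outer = outer_modes(7, system.media_depth, system.well_radius, system.slice_radius)
    base = baseline_profile(transport, system, surface_atm)
    return assemble_system(inner, outer, base)


class TestOverlapIntegrals:
    def test_homogeneous_limit_is_cosine_orthogonality(self, default_5mm, surface_atm):
        # with D1 = D2 and V = 0 the inner modes are the outer cosines, so
        # the overlap matrix must be (H/2) I
        system, _ = default_5mm
        transport = TransportParams(1.6e-9, 1.6e-9, 0.0)
        inner = find_inner_eigenvalues(transport, system, 5)
        outer = outer_modes(5, system.media_depth, system.well_radius, system.slice_radius)
        H = system.media_depth
        for m, im in enumerate(inner.modes):
            for n, om in enumerate(outer):
                val = overlap_integral(im, om)
                expected = H / 2.0 if m == n else 0.0
                assert val == pytest.approx(expected, abs=1e-12 * H)

    def test_panel_quadrature_agrees_with_adaptive(self, default_5mm, surface_atm):
        system, transport = default_5mm
        inner = find_inner_eigenvalues(transport, system, 7)
        outer = outer_modes(7, system.media_depth, system.well_radius, system.slice_radius)
        for m, n in ((0, 0), (2, 5), (6, 1)):
            a = overlap_integral(inner.modes[m], outer[n])
            b = overlap_integral_quad(inner.modes[m], outer[n])
            assert a == pytest.approx(b, rel=1e-10, abs=1e-16)

    def test_bottom_placement_drops_lower_band(self, surface_atm):
        # h1 = 0: the integral reduces to the two remaining pieces and the
        # two quadrature paths must still agree
        system, transport = default_parameters(placement="bottom")
        inner = find_inner_eigenvalues(transport, system, 4)
        outer = outer_modes(4, system.media_depth, system.well_radius, system.slice_radius)
        for m in range(4):
            a = overlap_integral(inner.modes[m], outer[m])
            b = overlap_integral_quad(inner.modes[m], outer[m])
            assert a == pytest.approx(b, rel=1e-10, abs=1e-16)


class TestProjectionLoad:
    def test_no_uptake_gives_zero_load(self, default_5mm, surface_atm):
        system, _ = default_5mm
        transport = TransportParams(4.85e-9, 1.6e-9, 0.0)
        inner = find_inner_eigenvalues(transport, system, 4)
        base = baseline_profile(transport, system, surface_atm)
        for mode in inner.modes:
            assert projection_load(mode, base) == pytest.approx(0.0, abs=1e-14)

    def test_linear_in_surface_pressure(self, default_5mm):
        system, transport = default_5mm
        inner = find_inner_eigenvalues(transport, system, 3)
        g1 = [projection_load(m, baseline_profile(transport, system,
                                                  SurfaceOxygen(0.21, 160.0)))
              for m in inner.modes]
        g2 = [projection_load(m, baseline_profile(transport, system,
                                                  SurfaceOxygen(0.42, 320.0)))
              for m in inner.modes]
        assert np.allclose(g2, 2.0 * np.asarray(g1), rtol=1e-12)

    def test_panel_quadrature_agrees_with_adaptive(self, default_5mm, surface_atm):
        system, transport = default_5mm
        inner = find_inner_eigenvalues(transport, system, 5)
        base = baseline_profile(transport, system, surface_atm)
        for mode in inner.modes:
            a = projection_load(mode, base)
            b = projection_load_quad(mode, base)
            assert a == pytest.approx(b, rel=1e-10, abs=1e-14)


class TestAssembly:
    def test_entries_match_arbitrary_precision_naive_evaluation(self, assembled7):
        # undo the basis rescaling and compare each Bessel factor against
        # unscaled 50-digit evaluation
        ms = assembled7
        r_T = ms.system.slice_radius
        lams = ms.inner.eigenvalues
        O = ms.T  # T carries the raw Gram; recompute O from R instead
        for n, om in enumerate(ms.outer):
            f_naive = float(mp_radial_factor(om.omega, r_T, ms.system.well_radius))
            fp_naive = float(mp_radial_factor_derivative(om.omega, r_T,
                                                         ms.system.well_radius))
            scale = math.exp(om.log_norm)
            for m in range(ms.M):
                o_mn = overlap_integral(ms.inner.modes[m], om)
                assert ms.R[m, n] * scale == pytest.approx(f_naive * o_mn, rel=1e-9,
                                                           abs=1e-30)
                assert ms.S[m, n] * scale == pytest.approx(fp_naive * o_mn, rel=1e-9,
                                                           abs=1e-30)
        # the rescaled inner Bessel factor lambda I1(lam r_T)/I0(lam r_T)
        # must match 50-digit evaluation even where I0 itself is huge
        from scipy.special import ive
        for lam in lams:
            package_ratio = lam * ive(1, lam * r_T) / ive(0, lam * r_T)
            mp_ratio = lam * float(mp_i1(lam * r_T) / mp_i0(lam * r_T))
            assert package_ratio == pytest.approx(mp_ratio, rel=1e-12)

    def test_w_column_factor_vanishes_with_lambda(self):
        # lambda I0'(lambda r_T) -> 0 as lambda -> 0
        from scipy.special import ive
        lam = np.array([1e-8, 1e-4, 1e-2])
        vals = lam * ive(1, lam * 2.5e-3) / ive(0, lam * 2.5e-3)
        # small-argument behaviour lambda^2 r_T / 2
        assert np.allclose(vals, lam**2 * 2.5e-3 / 2.0, rtol=1e-6)
        assert vals[0] < 1e-18

    def test_row_scaling_leaves_coefficients_unchanged(self, assembled7):
        # scaling test-function row m of every matrix and the load by c is a
        # pure row operation on the linear system
        ms = assembled7
        sol_ref = solve_coefficients(ms)
        c = np.ones(ms.M)
        c[2] = 7.5
        scaled = MatchingSystem(
            R=ms.R * c[:, None], S=ms.S * c[:, None], T=ms.T * c[:, None],
            W=ms.W * c[:, None], g=ms.g * c, M=ms.M, inner=ms.inner,
            outer=ms.outer, baseline=ms.baseline, system=ms.system,
            params=ms.params, phi0=ms.phi0)
        sol_scaled = solve_coefficients(scaled)
        assert np.allclose(sol_scaled.alpha_hat, sol_ref.alpha_hat, rtol=1e-10)
        assert np.allclose(sol_scaled.A_hat, sol_ref.A_hat, rtol=1e-10)


class TestSolve:
    def test_no_uptake_gives_trivial_coefficients(self, default_5mm, surface_atm):
        system, _ = default_5mm
        transport = TransportParams(4.85e-9, 1.6e-9, 0.0)
        inner = find_inner_eigenvalues(transport, system, 5)
        outer = outer_modes(5, system.media_depth, system.well_radius, system.slice_radius)
        base = baseline_profile(transport, system, surface_atm)
        sol = solve_coefficients(assemble_system(inner, outer, base))
        assert np.allclose(sol.alpha_hat, 0.0, atol=1e-14)
        assert np.allclose(sol.A_hat, 0.0, atol=1e-14)

    def test_matching_equation_residuals_small(self, sol7_middle5, sol40_middle5):
        for sol in (sol7_middle5, sol40_middle5):
            assert sol.residuals["value"] <= 1e-8
            assert sol.residuals["flux"] <= 1e-8

    def test_both_elimination_routes_agree(self, sol7_middle5, sol40_middle5):
        assert sol7_middle5.residuals["route_diff"] <= 1e-8
        assert sol40_middle5.residuals["route_diff"] <= 1e-8

    def test_rim_concentration_jump_small_when_converged(self, sol40_middle5):
        sysg = sol40_middle5.system
        z = np.linspace(0.0, sysg.media_depth, 50)
        r_T = sysg.slice_radius
        inner_vals = np.asarray(sol40_middle5.evaluate(r_T * (1 - 1e-9), z))
        outer_vals = np.asarray(sol40_middle5.evaluate(r_T * (1 + 1e-9), z))
        assert np.abs(inner_vals - outer_vals).max() <= 0.005 * 160.0

    def test_rim_mismatch_decreases_with_truncation(self, default_5mm, surface_atm):
        system, transport = default_5mm
        z = np.linspace(0.0, system.media_depth, 400)
        r_T = system.slice_radius
        mismatch = []
        for M in (5, 7, 10, 20, 40):
            sol = solve_oxygen_field(system, transport, surface_atm, M=M)
            iv = np.asarray(sol.evaluate(r_T * (1 - 1e-9), z))
            ov = np.asarray(sol.evaluate(r_T * (1 + 1e-9), z))
            mismatch.append(float(np.sqrt(np.mean((iv - ov) ** 2))))
        assert all(b <= a * (1 + 1e-9) for a, b in zip(mismatch, mismatch[1:]))

    def test_solution_linear_in_surface_pressure(self, default_5mm):
        system, transport = default_5mm
        s1 = solve_oxygen_field(system, transport, SurfaceOxygen(0.21, 160.0), M=7)
        s2 = solve_oxygen_field(system, transport, SurfaceOxygen(0.42, 320.0), M=7)
        r = np.linspace(0, system.well_radius, 7)
        z = np.linspace(0, system.media_depth, 7)
        f1 = np.asarray(s1.evaluate(r[:, None], z[None, :]))
        f2 = np.asarray(s2.evaluate(r[:, None], z[None, :]))
        assert np.allclose(f2, 2.0 * f1, rtol=1e-9)

    def test_literal_coefficient_conversion_roundtrip(self, sol7_middle5):
        # alpha_hat = alpha * I0(lambda r_T): converting back and forth must
        # reproduce the stored rescaled coefficients for moderate orders
        from scipy.special import iv
        lams = sol7_middle5.inner.eigenvalues
        r_T = sol7_middle5.system.slice_radius
        alpha = sol7_middle5.alpha_literal()
        assert np.allclose(alpha * iv(0, lams * r_T), sol7_middle5.alpha_hat, rtol=1e-10)
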