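import math

import numpy as np
import pytest

from pcls_oxygen import SurfaceOxygen, TransportParams, default_parameters
from pcls_oxygen.inner import (
    baseline_profile,
    dispersion_residual,
    find_inner_eigenvalues,
    relative_dispersion_residual,
)

from oracles import baseline_1d_fd, count_dispersion_roots


@pytest.fixture(scope="module")
def eig7(default_5mm):
    system, transport = default_5mm
    return find_inner_eigenvalues(transport, system, 7)


class TestBaselineProfile:
    def test_boundary_conditions(self, default_5mm, surface_atm):
        system, transport = default_5mm
        U = baseline_profile(transport, system, surface_atm)
        assert U(system.media_depth) == pytest.approx(160.0, rel=1e-12)
        # no-flux floor: symmetric difference derivative at z=0 via the constant piece
        assert U.derivative(0.0) == 0.0

    def test_interface_continuity(self, default_5mm, surface_atm):
        # compare the one-sided piece formulas exactly at the faces
        system, transport = default_5mm
        U = baseline_profile(transport, system, surface_atm)
        k = transport.k
        base = transport.d_media * 160.0 / U.theta
        slope = transport.d_tissue * k * math.sinh(k * system.thickness) / U.theta
        # value continuity: constant piece vs tissue piece at h1,
        # tissue piece vs linear piece at h2
        assert U(system.h1) == pytest.approx(base, rel=1e-12)
        above_h2 = 160.0 * (1.0 + slope * (system.h2 - system.media_depth))
        assert U(system.h2) == pytest.approx(above_h2, rel=1e-9)
        # D-weighted flux continuity: zero flux at h1 (constant below),
        # D2 * inside'(h2) = D1 * above'(h2)
        assert transport.d_tissue * U.derivative(system.h1) == pytest.approx(0.0, abs=1e-12)
        inside_flux = transport.d_tissue * base * k * math.sinh(k * system.thickness)
        above_flux = transport.d_media * 160.0 * slope
        assert inside_flux == pytest.approx(above_flux, rel=1e-12)

    def test_no_uptake_gives_uniform_profile(self, default_5mm, surface_atm):
        system, _ = default_5mm
        transport = TransportParams(4.85e-9, 1.6e-9, 0.0)
        U = baseline_profile(transport, system, surface_atm)
        z = np.linspace(0, system.media_depth, 50)
        assert np.allclose(U(z), 160.0, rtol=1e-12)

    def test_monotone_nondecreasing_for_uptake(self, default_5mm, surface_atm):
        system, transport = default_5mm
        U = baseline_profile(transport, system, surface_atm)
        z = np.linspace(0, system.media_depth, 500)
        assert np.all(np.diff(U(z)) >= -1e-9)

    def test_against_independent_1d_fd_solve(self, surface_atm):
        # slice resting on the bottom of the well; compare the floor value
        system, transport = default_parameters(placement="bottom")
        U = baseline_profile(transport, system, surface_atm)
        zc, phi = baseline_1d_fd(transport.d_media, transport.d_tissue,
                                 transport.uptake_rate, system.media_depth,
                                 system.h1, system.h2, 160.0, n=20001)
        assert np.asarray(U(zc)) == pytest.approx(phi, abs=2e-3 * 160.0)
        assert U(0.0) == pytest.approx(phi[0], abs=1e-3 * 160.0)


class TestDispersionRelation:
    def test_homogeneous_column_reduces_to_quarter_wave_modes(self, default_5mm):
        # D1 = D2, V = 0: eigenvalues must be (n - 1/2) pi / H exactly
        system, _ = default_5mm
        transport = TransportParams(1.6e-9, 1.6e-9, 0.0)
        eig = find_inner_eigenvalues(transport, system, 5)
        H = system.media_depth
        expected = (np.arange(1, 6) - 0.5) * math.pi / H
        assert eig.eigenvalues == pytest.approx(expected, rel=1e-10)

    def test_trapped_root_count_matches_dense_scan(self, default_5mm):
        system, transport = default_5mm
        k = transport.k
        n_scan = count_dispersion_roots(
            lambda lam: dispersion_residual(lam, transport, system),
            1e-3 * k, k * (1 - 1e-9), n_samples=100_000)
        eig = find_inner_eigenvalues(transport, system, 12)
        assert eig.trapped_count == n_scan
        assert eig.trapped_count == 6  # k ~ 5968.7 1/m, spacing ~ pi/H

    def test_bottom_placement_degenerate_form(self, surface_atm):
        # h1 = 0 removes the lower fluid band; roots must still match a scan
        system, transport = default_parameters(placement="bottom")
        eig = find_inner_eigenvalues(transport, system, 8)
        lam_max = eig.eigenvalues[-1]
        n_scan = count_dispersion_roots(
            lambda lam: dispersion_residual(lam, transport, system),
            1e-3 * transport.k, lam_max * 1.001, n_samples=200_000)
        assert n_scan == 8

    def test_residual_vanishes_at_returned_eigenvalues(self, eig7):
        assert np.all(relative_dispersion_residual(eig7) < 1e-10)

    def test_branch_consistency_enforced(self, default_5mm):
        system, transport = default_5mm
        with pytest.raises(ValueError):
            dispersion_residual(transport.k * 2, transport, system, branch="trapped")


class TestEigenfunctions:
    def test_normalisation_and_surface_zero(self, eig7):
        H = eig7.system.media_depth
        for mode in eig7.modes:
            assert mode(0.0) == pytest.approx(1.0, rel=1e-12)
            assert abs(mode(H)) < 1e-10

    def test_floor_derivative_zero(self, eig7):
        for mode in eig7.modes:
            assert mode.derivative(0.0) == 0.0

    def test_interface_continuity_and_weighted_flux(self, eig7):
        # one-sided piece formulas evaluated exactly at the faces
        p, g = eig7.params, eig7.system
        for mode in eig7.modes:
            lam = mode.lam
            scale = max(1.0, np.max(np.abs(mode(np.linspace(0, g.media_depth, 200)))))
            # h1: lower fluid piece vs tissue piece (mode() selects the
            # tissue branch at z = h1)
            assert mode(g.h1) == pytest.approx(math.cos(lam * g.h1), abs=1e-10 * scale)
            assert p.d_media * (-lam * math.sin(lam * g.h1)) == pytest.approx(
                p.d_tissue * mode.derivative(g.h1), abs=1e-8 * p.d_media * lam * scale)
            # h2: tissue piece vs upper fluid piece (closure coefficient rho)
            top_val = mode.rho * math.sin(lam * (g.h2 - g.media_depth))
            top_der = mode.rho * lam * math.cos(lam * (g.h2 - g.media_depth))
            assert mode(g.h2) == pytest.approx(top_val, abs=1e-8 * scale)
            assert p.d_tissue * mode.derivative(g.h2) == pytest.approx(
                p.d_media * top_der, abs=1e-8 * p.d_media * lam * scale)

    def test_derivative_agrees_with_finite_differences(self, eig7):
        g = eig7.system
        mode = eig7.modes[3]
        # interior points of each piece
        for z in (0.5 * g.h1, 0.5 * (g.h1 + g.h2), 0.5 * (g.h2 + g.media_depth)):
            dz = 1e-9
            fd = (mode(z + dz) - mode(z - dz)) / (2 * dz)
            assert mode.derivative(z) == pytest.approx(fd, rel=1e-5, abs=1e-6 * mode.lam)

    def test_eigenvalues_strictly_increasing_and_separated(self, eig7):
        lams = eig7.eigenvalues
        spacing = math.pi / eig7.system.media_depth
        assert np.all(np.diff(lams) > 0.1 * spacing)

    def test_weighted_orthogonality(self, eig7):
        # int_0^H D(z) Z_m Z_n dz = 0 for m != n (Sturm-Liouville weight D)
        p, g = eig7.params, eig7.system
        pieces = [(0.0, g.h1, p.d_media), (g.h1, g.h2, p.d_tissue),
                  (g.h2, g.media_depth, p.d_media)]
        from scipy.integrate import simpson

        M = len(eig7.modes)
        gram = np.zeros((M, M))
        for z0, z1, D in pieces:
            z = np.linspace(z0, z1, 4001)
            Z = np.vstack([m(z) for m in eig7.modes])
            for a in range(M):
                for b in range(M):
                    gram[a, b] += D * simpson(Z[a] * Z[b], x=z)
        diag = np.abs(np.diag(gram))
        off = np.abs(gram - np.diag(np.diag(gram)))
        assert off.max() <= 1e-8 * diag.max()

    def test_domain_error_outside_column(self, eig7):
        from pcls_oxygen.inner import inner_eigenfunction
        with pytest.raises(ValueError):
            inner_eigenfunction(eig7.modes[0], -1e-4)
        with pytest.raises(ValueError):
            inner_eigenfunction(eig7.modes[0], eig7.system.media_depth * 1.01)
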