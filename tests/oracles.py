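"""Independent numerical oracles used by the test suite.

These share no code path with the package's solvers: a two-layer 1-D
finite-difference column solve, brute-force dispersion-root counting by
dense sign-change scanning, and arbitrary-precision Bessel evaluation via
mpmath.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_banded


def baseline_1d_fd(d_media, d_tissue, uptake_rate, H, h1, h2, phi0, n=20001):
    """Two-layer 1-D column oxygen profile by cell-centred finite volumes.

    Solves (D(z) phi')' - V 1_[h1,h2] phi = 0 with phi'(0)=0, phi(H)=phi0 on
    an interface-aligned mesh with harmonic-mean face diffusivities.
    Returns (z_centers, phi).
    """
    # edges aligned with h1, h2
    segs = [(0.0, h1), (h1, h2), (h2, H)]
    lens = np.array([b - a for a, b in segs])
    alloc = np.maximum(2, np.round(n * lens / lens.sum()).astype(int))
    edges = [np.array([0.0])]
    for (a, b), m in zip(segs, alloc):
        if b > a:
            edges.append(np.linspace(a, b, m + 1)[1:])
    e = np.concatenate(edges)
    zc = 0.5 * (e[:-1] + e[1:])
    dz = np.diff(e)
    nc = len(zc)
    tissue = (e[:-1] >= h1 - 1e-15) & (e[1:] <= h2 + 1e-15)
    D = np.where(tissue, d_tissue, d_media)

    lower = np.zeros(nc)
    diag = np.zeros(nc)
    upper = np.zeros(nc)
    rhs = np.zeros(nc)
    # interior faces
    dist0 = e[1:-1] - zc[:-1]
    dist1 = zc[1:] - e[1:-1]
    g = 1.0 / (dist0 / D[:-1] + dist1 / D[1:])
    diag[:-1] += g
    diag[1:] += g
    lower[:-1] = -g      # sub-diagonal entries for rows 1..nc-1
    upper[1:] = -g       # super-diagonal entries for rows 0..nc-2
    # top Dirichlet
    gt = D[-1] / (dz[-1] / 2.0)
    diag[-1] += gt
    rhs[-1] += gt * phi0
    # uptake
    diag += uptake_rate * dz * tissue

    ab = np.zeros((3, nc))
    ab[0, 1:] = upper[1:]
    ab[1, :] = diag
    ab[2, :-1] = lower[:-1]
    phi = solve_banded((1, 1), ab, rhs)
    return zc, phi


def count_dispersion_roots(fun, lo, hi, n_samples=100_000):
    """Number of sign changes of ``fun`` on (lo, hi) from a dense scan."""
    grid = np.linspace(lo, hi, n_samples)
    vals = np.asarray(fun(grid))
    sign = np.sign(vals)
    return int(np.sum(sign[:-1] * sign[1:] < 0))


def mp_radial_factor(omega, r, r_o, dps=50):
    """Arbitrary-precision K0'(w r_o) I0(w r) - I0'(w r_o) K0(w r)."""
    import mpmath as mp

    with mp.workdps(dps):
        w = mp.mpf(omega)
        val = (-mp.besselk(1, w * r_o) * mp.besseli(0, w * r)
               - mp.besseli(1, w * r_o) * mp.besselk(0, w * r))
        return val


def mp_radial_factor_derivative(omega, r, r_o, dps=50):
    """Arbitrary-precision d/dr of the wall-condition radial combination."""
    import mpmath as mp

    with mp.workdps(dps):
        w = mp.mpf(omega)
        val = w * (-mp.besselk(1, w * r_o) * mp.besseli(1, w * r)
                   + mp.besseli(1, w * r_o) * mp.besselk(1, w * r))
        return val


def mp_i0(x, dps=50):
    import mpmath as mp

    with mp.workdps(dps):
        return mp.besseli(0, mp.mpf(x))


def mp_i1(x, dps=50):
    import mpmath as mp

    with mp.workdps(dps):
        return mp.besseli(1, mp.mpf(x))
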