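"""Outer-region (fluid annulus) eigenfunctions and radial basis.

The annulus ``r_T < r < r_o`` contains only media, so the field there is
``phi_I(r, z) = phi0 + sum_n A_n f_n(r) cos(omega_n z)`` with
``omega_n = (n - 1/2) pi / H`` forced by the surface Dirichlet and bottom
no-flux conditions, and the radial combination

    f_n(r) = K0'(omega_n r_o) I0(omega_n r) - I0'(omega_n r_o) K0(omega_n r)

whose derivative vanishes at the well wall ``r = r_o``.

Numerics: for large ``omega_n r`` the modified Bessel functions overflow, so
all evaluation goes through exponentially scaled functions (``ive``/``kve``)
with the exponential factors combined analytically.  The basis is rescaled
so that ``f_n(r_T)`` is O(1): each mode stores ``log N_n`` with
``N_n = I1(omega_n r_o) K0(omega_n r_T)`` and exposes
``f_n(r) / N_n``; only ratios bounded on ``[r_T, r_o]`` are ever formed.
Coefficients solved in the rescaled basis relate to the literal ones by
``A_n = A_hat_n / N_n``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ive, kve

__all__ = ["OuterMode", "outer_eigenvalues", "outer_modes", "outer_radial_factor",
           "outer_radial_factor_naive"]


def outer_eigenvalues(M: int, H: float) -> np.ndarray:
    """Vertical eigen-wavenumbers ``omega_n = (n - 1/2) pi / H``, n = 1..M."""
    if M < 1:
        raise ValueError("M must be >= 1")
    if H <= 0.0:
        raise ValueError("H must be positive")
    return (np.arange(1, M + 1) - 0.5) * math.pi / H


@dataclass(frozen=True)
class OuterMode:
    """One annulus mode: vertical wavenumber plus the scaled radial factor."""

    index: int
    omega: float
    well_radius: float
    slice_radius: float
    #: log of the rescaling constant N = I1(omega r_o) K0(omega r_T)
    log_norm: float = field(init=False)
    _c1: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        w, r_o, r_T = self.omega, self.well_radius, self.slice_radius
        log_norm = (math.log(ive(1, w * r_o)) + math.log(kve(0, w * r_T))
                    + w * (r_o - r_T))
        # prefactor of the I0-type (wall-reflected) term relative to N
        c1 = kve(1, w * r_o) / (ive(1, w * r_o) * kve(0, w * r_T))
        object.__setattr__(self, "log_norm", float(log_norm))
        object.__setattr__(self, "_c1", float(c1))

    def radial(self, r):
        """Scaled radial factor ``f(r) / N`` for ``r in (0, r_o]``.

        Bounded on ``[r_T, r_o]``; decays like ``exp(-omega (r_T - r))``
        relative terms are kept explicit so no overflow can occur there.
        """
        w, r_o, r_T = self.omega, self.well_radius, self.slice_radius
        r = np.asarray(r, dtype=float)
        if np.any(r <= 0.0):
            raise ValueError("outer radial factor requires r > 0")
        t1 = self._c1 * ive(0, w * r) * np.exp(w * (r + r_T - 2.0 * r_o))
        t2 = (kve(0, w * r) / kve(0, w * r_T)) * np.exp(-w * (r - r_T))
        out = -(t1 + t2)
        return out if out.ndim else float(out)

    def radial_derivative(self, r):
        """d/dr of the scaled radial factor; zero at ``r = r_o``."""
        w, r_o, r_T = self.omega, self.well_radius, self.slice_radius
        r = np.asarray(r, dtype=float)
        if np.any(r <= 0.0):
            raise ValueError("outer radial factor requires r > 0")
        t1 = self._c1 * ive(1, w * r) * np.exp(w * (r + r_T - 2.0 * r_o))
        t2 = (kve(1, w * r) / kve(0, w * r_T)) * np.exp(-w * (r - r_T))
        out = w * (-t1 + t2)
        return out if out.ndim else float(out)

    def vertical(self, z):
        return np.cos(self.omega * np.asarray(z, dtype=float))


def outer_modes(M: int, H: float, well_radius: float, slice_radius: float) -> tuple[OuterMode, ...]:
    """Build the first ``M`` annulus modes."""
    omegas = outer_eigenvalues(M, H)
    return tuple(
        OuterMode(index=n + 1, omega=float(w), well_radius=well_radius,
                  slice_radius=slice_radius)
        for n, w in enumerate(omegas)
    )


def outer_radial_factor(mode: OuterMode, r, well_radius: float | None = None):
    """Scaled wall-condition radial combination of ``mode`` at radius ``r``.

    Thin functional wrapper over :meth:`OuterMode.radial`; ``well_radius``
    is accepted for signature symmetry and checked against the mode.
    """
    if well_radius is not None and not math.isclose(well_radius, mode.well_radius):
        raise ValueError("well_radius does not match the mode")
    return mode.radial(r)


def outer_radial_factor_naive(omega: float, r, well_radius: float):
    """Unscaled reference evaluation ``K0'(w r_o) I0(w r) - I0'(w r_o) K0(w r)``
    via plain ``iv``/``kv``.  Overflows for large ``omega r``; kept for
    cross-checks at moderate arguments."""
    from scipy.special import iv, kv

    r = np.asarray(r, dtype=float)
    return -kv(1, omega * well_radius) * iv(0, omega * r) - iv(1, omega * well_radius) * kv(0, omega * r)
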