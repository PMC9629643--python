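"""Vertical eigensystem of the inner region (fluid-tissue-fluid column).

The inner region is the cylinder ``0 <= r < r_T`` containing the slice.  The
oxygen field there is written as ``phi_II(r, z) = U_II(z) + sum_n alpha_n
I0(lambda_n r) Z_n(z)`` where ``U_II`` is the one-dimensional baseline
profile of the layered column and the ``Z_n`` solve the piecewise
Sturm-Liouville problem

    Z'' + lambda^2 Z = 0          in the fluid bands,
    Z'' + (lambda^2 - k^2) Z = 0  in the tissue band  (k^2 = V / D2),

with ``Z'(0) = 0``, ``Z(H) = 0``, value continuity at ``h1`` and ``h2`` and
D-weighted flux continuity ``D1 Z'(fluid side) = D2 Z'(tissue side)``.
Writing the problem as ``(D Z')' + (lambda^2 D - V 1_tissue) Z = 0`` shows it
is self-adjoint with weight ``D(z)``, so eigenvalues are real and simple and
eigenfunctions are orthogonal under that weight.

Eigenvalues below ``k`` ("trapped" modes) behave hyperbolically inside the
tissue; those above ``k`` ("free" modes) oscillate everywhere.  Both branches
are roots of a single dispersion function that is analytic across
``lambda = k``, which is what :func:`dispersion_residual` evaluates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .params import SurfaceOxygen, TransportParams, WellSystem

__all__ = [
    "BaselineProfile",
    "InnerMode",
    "InnerEigensystem",
    "EigenvalueSearchError",
    "baseline_profile",
    "dispersion_residual",
    "find_inner_eigenvalues",
    "inner_eigenfunction",
]


class EigenvalueSearchError(RuntimeError):
    """Raised when the requested number of eigenvalues cannot be bracketed."""


def _cs(x, s):
    """Pair ``(C, S)`` solving ``y'' = -s y`` with ``C(0)=1, C'(0)=0`` and
    ``S(0)=0, S'(0)=1``.

    For ``s > 0`` this is ``(cos(q x), sin(q x)/q)`` with ``q = sqrt(s)``;
    for ``s < 0`` the hyperbolic analogue; for ``s = 0`` the pair ``(1, x)``.
    The pair is jointly analytic in ``s``, which lets the trapped and free
    branches of the vertical problem share one set of formulas.  Derivatives:
    ``C' = -s S`` and ``S' = C``.
    """
    x = np.asarray(x, dtype=float)
    s_arr = np.asarray(s, dtype=float)
    q = np.sqrt(np.abs(s_arr))
    y = q * x
    # np.where evaluates both branches: clamp the hyperbolic argument so the
    # unused branch cannot overflow.
    yh = np.minimum(y, 700.0)
    C = np.where(s_arr >= 0.0, np.cos(y), np.cosh(yh))
    q_safe = np.where(q == 0.0, 1.0, q)
    S = np.where(
        s_arr > 0.0,
        np.sin(y) / q_safe,
        np.where(s_arr < 0.0, np.sinh(yh) / q_safe, x),
    )
    return C, S


# ---------------------------------------------------------------------------
# baseline 1-D profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaselineProfile:
    """One-dimensional layered-column oxygen profile ``U_II(z)``.

    Piecewise: constant ``D1 phi0 / theta`` below the slice, ``(D1 phi0 /
    theta) cosh(k (z - h1))`` inside it, and linear in the media above, with
    the composite conductance

        theta = D1 cosh(k (h2 - h1)) + D2 k (H - h2) sinh(k (h2 - h1)).

    Satisfies ``U(H) = phi0``, ``U'(0) = 0``, value continuity and D-weighted
    flux continuity at both faces.  For ``V = 0`` it degenerates to the
    constant ``phi0``.
    """

    params: TransportParams
    system: WellSystem
    phi0: float
    theta: float = field(init=False)

    def __post_init__(self) -> None:
        p, s = self.params, self.system
        k = p.k
        dh = s.h2 - s.h1
        theta = p.d_media * math.cosh(k * dh) + p.d_tissue * k * (s.media_depth - s.h2) * math.sinh(k * dh)
        object.__setattr__(self, "theta", theta)

    def __call__(self, z):
        p, s = self.params, self.system
        k = p.k
        z = np.asarray(z, dtype=float)
        base = p.d_media * self.phi0 / self.theta
        slope = p.d_tissue * k * math.sinh(k * (s.h2 - s.h1)) / self.theta
        below = base * np.ones_like(z)
        inside = base * np.cosh(k * np.clip(z - s.h1, 0.0, s.h2 - s.h1))
        above = self.phi0 * (1.0 + slope * (z - s.media_depth))
        out = np.where(z < s.h1, below, np.where(z <= s.h2, inside, above))
        return out if out.ndim else float(out)

    def derivative(self, z):
        """dU/dz [mmHg/m]."""
        p, s = self.params, self.system
        k = p.k
        z = np.asarray(z, dtype=float)
        base = p.d_media * self.phi0 / self.theta
        inside = base * k * np.sinh(k * np.clip(z - s.h1, 0.0, s.h2 - s.h1))
        above = self.phi0 * p.d_tissue * k * math.sinh(k * (s.h2 - s.h1)) / self.theta
        out = np.where(z < s.h1, 0.0, np.where(z <= s.h2, inside, above))
        return out if out.ndim else float(out)


def baseline_profile(params: TransportParams, system: WellSystem,
                     surface: SurfaceOxygen) -> BaselineProfile:
    """Build the 1-D baseline profile for the given column and surface oxygen."""
    return BaselineProfile(params, system, surface.phi0)


# ---------------------------------------------------------------------------
# dispersion relation
# ---------------------------------------------------------------------------

def dispersion_residual(lam, params: TransportParams, system: WellSystem,
                        branch: str | None = None):
    """Pole-free dispersion function whose positive roots are the vertical
    eigenvalues.

    Built directly from the interface conditions at ``h2``: with
    ``Z`` normalised to ``cos(lambda z)`` below the slice, the middle-piece
    value ``Zm`` and derivative ``Zp`` at ``h2`` must connect to the top
    piece ``rho sin(lambda (z - H))``, giving

        F(lambda) = D2 Zp(h2) sin(lambda (h2 - H))
                    - D1 lambda cos(lambda (h2 - H)) Zm(h2).

    Multiplying the textbook tangent form through by its cosine denominators
    yields the same function up to a nonzero smooth factor, so sign changes
    of ``F`` bracket exactly the tangent-form roots while avoiding tangent
    poles.  ``F`` is analytic across ``lambda = k`` and covers both the
    trapped and free branches.

    ``branch`` (``"trapped"``/``"free"``) is an optional consistency check
    against the sign of ``lambda - k``.
    """
    lam = np.asarray(lam, dtype=float)
    p, g = params, system
    k = p.k
    if branch is not None:
        if branch not in ("trapped", "free"):
            raise ValueError(f"unknown branch {branch!r}")
        if branch == "trapped" and np.any(lam >= k):
            raise ValueError("trapped branch requires lambda < k")
        if branch == "free" and np.any(lam <= k):
            raise ValueError("free branch requires lambda > k")
    s = lam * lam - k * k
    dh = g.h2 - g.h1
    C, S = _cs(dh, s)
    a = np.cos(lam * g.h1)
    b = (p.d_media * lam / p.d_tissue) * np.sin(lam * g.h1)
    zm = a * C - b * S            # middle-piece value at h2
    zp = -s * a * S - b * C       # middle-piece derivative at h2
    arg = lam * (g.h2 - g.media_depth)
    F = p.d_tissue * zp * np.sin(arg) - p.d_media * lam * np.cos(arg) * zm
    return F if F.ndim else float(F)


def _residual_scale(lam, params: TransportParams, system: WellSystem):
    """Magnitude scale of the dispersion function's individual terms, for
    forming a relative residual."""
    lam = np.asarray(lam, dtype=float)
    p, g = params, system
    s = lam * lam - p.k**2
    dh = g.h2 - g.h1
    C, S = _cs(dh, s)
    a = np.cos(lam * g.h1)
    b = (p.d_media * lam / p.d_tissue) * np.sin(lam * g.h1)
    t1 = np.abs(p.d_tissue * (-s * a * S - b * C))
    t2 = np.abs(p.d_media * lam * (a * C - b * S))
    return np.maximum(t1 + t2, np.finfo(float).tiny)


# ---------------------------------------------------------------------------
# eigenmodes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InnerMode:
    """One vertical eigenmode of the inner column.

    ``lam`` is the eigen-wavenumber [1/m]; ``branch`` is ``"trapped"``
    (``lam < k``, hyperbolic inside the tissue) or ``"free"``.  ``rho`` is
    the closure coefficient of the top fluid piece (the printed trapped/free
    closure coefficients evaluated robustly).  The mode is normalised to
    ``Z(0) = 1``.
    """

    index: int
    lam: float
    branch: str
    params: TransportParams
    system: WellSystem
    rho: float = field(init=False)

    def __post_init__(self) -> None:
        p, g = self.params, self.system
        lam = self.lam
        s = lam * lam - p.k**2
        dh = g.h2 - g.h1
        C, S = _cs(dh, s)
        a = math.cos(lam * g.h1)
        b = (p.d_media * lam / p.d_tissue) * math.sin(lam * g.h1)
        zm = a * C - b * S
        zp = -s * a * S - b * C
        arg = lam * (g.h2 - g.media_depth)
        sin_a, cos_a = math.sin(arg), math.cos(arg)
        # The two interface conditions give two equivalent expressions for
        # rho; pick the better conditioned denominator (they agree at a root
        # of the dispersion function).
        if abs(sin_a) >= abs(cos_a):
            rho = zm / sin_a
        else:
            rho = p.d_tissue * zp / (p.d_media * lam * cos_a)
        object.__setattr__(self, "rho", float(rho))

    @property
    def aux(self) -> float:
        """tau = sqrt(k^2 - lam^2) (trapped) or delta = sqrt(lam^2 - k^2)
        (free), the tissue-interior wavenumber [1/m]."""
        return math.sqrt(abs(self.lam**2 - self.params.k**2))

    def __call__(self, z):
        p, g = self.params, self.system
        lam = self.lam
        s = lam * lam - p.k**2
        z = np.asarray(z, dtype=float)
        zc = np.clip(z - g.h1, 0.0, g.h2 - g.h1)
        C, S = _cs(zc, s)
        a = np.cos(lam * g.h1)
        b = (p.d_media * lam / p.d_tissue) * np.sin(lam * g.h1)
        below = np.cos(lam * z)
        inside = a * C - b * S
        above = self.rho * np.sin(lam * (z - g.media_depth))
        out = np.where(z < g.h1, below, np.where(z <= g.h2, inside, above))
        return out if out.ndim else float(out)

    def derivative(self, z):
        p, g = self.params, self.system
        lam = self.lam
        s = lam * lam - p.k**2
        z = np.asarray(z, dtype=float)
        zc = np.clip(z - g.h1, 0.0, g.h2 - g.h1)
        C, S = _cs(zc, s)
        a = np.cos(lam * g.h1)
        b = (p.d_media * lam / p.d_tissue) * np.sin(lam * g.h1)
        below = -lam * np.sin(lam * z)
        inside = -s * a * S - b * C
        above = self.rho * lam * np.cos(lam * (z - g.media_depth))
        out = np.where(z < g.h1, below, np.where(z <= g.h2, inside, above))
        return out if out.ndim else float(out)


def inner_eigenfunction(mode: InnerMode, z):
    """Evaluate a vertical eigenfunction at ``z`` (``0 <= z <= H``)."""
    z_arr = np.asarray(z, dtype=float)
    H = mode.system.media_depth
    if np.any(z_arr < 0.0) or np.any(z_arr > H * (1.0 + 1e-12)):
        raise ValueError(f"z must lie in [0, {H}]")
    return mode(z)


@dataclass(frozen=True)
class InnerEigensystem:
    """Ordered collection of inner vertical modes."""

    modes: tuple[InnerMode, ...]
    params: TransportParams
    system: WellSystem

    @property
    def k(self) -> float:
        return self.params.k

    @property
    def eigenvalues(self) -> np.ndarray:
        return np.array([m.lam for m in self.modes])

    @property
    def trapped_count(self) -> int:
        return sum(1 for m in self.modes if m.branch == "trapped")

    def __len__(self) -> int:
        return len(self.modes)

    def to_dataframe(self):
        """Diagnostic table of eigenvalues, branches and relative dispersion
        residuals (one row per mode), for CSV export."""
        import pandas as pd

        res = relative_dispersion_residual(self)
        return pd.DataFrame({
            "index": [m.index for m in self.modes],
            "lambda_per_m": [m.lam for m in self.modes],
            "branch": [m.branch for m in self.modes],
            "tissue_wavenumber_per_m": [m.aux for m in self.modes],
            "closure_rho": [m.rho for m in self.modes],
            "relative_residual": res,
        })


def _count_estimate(lam: float, params: TransportParams, system: WellSystem) -> float:
    """WKB-style estimate of the number of eigenvalues below ``lam``."""
    g = system
    dh = g.h2 - g.h1
    fluid = g.media_depth - dh
    delta = math.sqrt(max(lam**2 - params.k**2, 0.0))
    return (lam * fluid + delta * dh) / math.pi


def find_inner_eigenvalues(
    params: TransportParams,
    system: WellSystem,
    M: int,
    *,
    points_per_spacing: int = 2000,
) -> InnerEigensystem:
    """Locate the ``M`` smallest vertical eigenvalues.

    Strategy: dense uniform scan of the pole-free dispersion function
    (``points_per_spacing`` samples per asymptotic mode spacing ``pi/H``),
    sign-change bracketing, then Brent root polishing to near machine
    precision.  The search window is widened geometrically if it turns out to
    hold fewer than ``M`` roots.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    H = system.media_depth
    spacing = math.pi / H
    k = params.k

    # initial window from the WKB counting estimate
    lam_hi = spacing
    while _count_estimate(lam_hi, params, system) < M + 3:
        lam_hi += spacing
    lam_hi = max(lam_hi, k + 2 * spacing)

    def F(lam):
        return dispersion_residual(lam, params, system)

    roots: list[float] = []
    for _attempt in range(8):
        n_pts = int(points_per_spacing * lam_hi / spacing) + 2
        grid = np.linspace(spacing * 1e-6, lam_hi, n_pts)
        vals = dispersion_residual(grid, params, system)
        sign = np.sign(vals)
        idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
        roots = []
        for i in idx:
            root = brentq(F, grid[i], grid[i + 1], xtol=1e-14 * max(grid[i + 1], 1.0),
                          rtol=8.9e-16, maxiter=200)
            roots.append(float(root))
        exact = np.nonzero(vals == 0.0)[0]
        for i in exact:
            if grid[i] > 0:
                roots.append(float(grid[i]))
        roots = sorted(roots)
        # drop near-duplicates (a root sitting exactly on a grid point can be
        # found from both neighbouring intervals)
        dedup: list[float] = []
        for r in roots:
            if not dedup or r - dedup[-1] > 1e-9 * spacing:
                dedup.append(r)
        roots = dedup
        if len(roots) >= M:
            break
        lam_hi *= 1.5
    else:
        raise EigenvalueSearchError(
            f"found only {len(roots)} of {M} eigenvalues up to lambda={lam_hi:.6g} "
            f"(k={k:.6g}, H={H:.6g}); widen the search window"
        )

    modes = tuple(
        InnerMode(index=i + 1, lam=lam, branch="trapped" if lam < k else "free",
                  params=params, system=system)
        for i, lam in enumerate(roots[:M])
    )
    return InnerEigensystem(modes=modes, params=params, system=system)


def relative_dispersion_residual(eigensystem: InnerEigensystem) -> np.ndarray:
    """|F(lambda_n)| divided by the local magnitude of F's terms, one entry
    per mode.  Diagnostic used to confirm root quality."""
    lams = eigensystem.eigenvalues
    F = dispersion_residual(lams, eigensystem.params, eigensystem.system)
    return np.abs(F) / _residual_scale(lams, eigensystem.params, eigensystem.system)
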