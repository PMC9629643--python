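"""Experimental-design scenarios: placement search, sweeps, scenario grid.

The scenarios mirror the questions a slice-culture experimentalist asks:
where in the well must a slice sit for its internal oxygen to match the
physiological periportal-to-perivenous window (maximum 65 mmHg, minimum
35 mmHg); how do the extrema move as the slice descends; and how does the
media volume change the attainable minimum when the slice rides just below
the surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .field import (
    FieldProfile,
    TissueExtrema,
    centreline_extrema,
    midplane_profile,
    tissue_extrema,
)
from .matching import SeriesSolution, solve_oxygen_field
from .params import (
    TOP_CLEARANCE,
    InvalidGeometryError,
    SurfaceOxygen,
    TransportParams,
    WellSystem,
    default_parameters,
    media_depth_from_volume,
    standard_placements,
)

__all__ = [
    "Scenario",
    "ScenarioResult",
    "UnattainableTargetError",
    "solve_scenario",
    "find_placement_height",
    "depth_sweep",
    "volume_sweep",
    "run_scenario_grid",
    "table_placements",
    "PHYSIOLOGICAL_MAX_MMHG",
    "PHYSIOLOGICAL_MIN_MMHG",
]

#: Physiological liver oxygen window: periportal ~65 mmHg down to
#: perivenous ~35 mmHg.
PHYSIOLOGICAL_MAX_MMHG = 65.0
PHYSIOLOGICAL_MIN_MMHG = 35.0

SLICE_DIAMETERS = (5.0e-3, 8.0e-3)
OXYGEN_FRACTIONS = (0.21, 0.80, 0.95)
PLACEMENTS = ("bottom", "middle", "top")


class UnattainableTargetError(ValueError):
    """Raised when no slice placement can reach the requested extremum."""


@dataclass(frozen=True)
class Scenario:
    """One simulated experiment: slice diameter, incubator oxygen, placement."""

    slice_diameter: float          # [m]
    oxygen_fraction: float
    placement: str                 # bottom | middle | top
    M: int = 7

    def describe(self) -> dict:
        return {
            "slice_diameter_mm": self.slice_diameter * 1e3,
            "oxygen_percent": self.oxygen_fraction * 100.0,
            "placement": self.placement,
            "M": self.M,
        }


@dataclass(frozen=True)
class ScenarioResult:
    scenario: Scenario
    h1: float
    h2: float
    extrema: TissueExtrema
    midplane: FieldProfile
    solution: SeriesSolution


def _build(slice_radius: float, oxygen_fraction: float, h1: float, h2: float,
           media_depth: float | None = None,
           media_volume: float | None = None) -> tuple[WellSystem, TransportParams, SurfaceOxygen]:
    system, transport = default_parameters(slice_diameter=2 * slice_radius)
    if media_depth is not None:
        system = system.with_media_depth(media_depth, keep_placement=True,
                                         media_volume=media_volume)
    system = system.with_placement(h1, h2)
    return system, transport, SurfaceOxygen.from_fraction(oxygen_fraction)


def solve_scenario(scenario: Scenario) -> ScenarioResult:
    """Solve one named scenario under the reference 12-well configuration."""
    system, transport = default_parameters(slice_diameter=scenario.slice_diameter,
                                           placement=scenario.placement)
    surface = SurfaceOxygen.from_fraction(scenario.oxygen_fraction)
    sol = solve_oxygen_field(system, transport, surface, M=scenario.M)
    return ScenarioResult(
        scenario=scenario,
        h1=system.h1,
        h2=system.h2,
        extrema=tissue_extrema(sol),
        midplane=midplane_profile(sol),
        solution=sol,
    )


def find_placement_height(
    target: str,
    value: float,
    slice_radius: float = 2.5e-3,
    oxygen_fraction: float = 0.21,
    M: int = 40,
    h_tol: float = 1e-7,
    phi_tol: float = 0.01,
) -> tuple[float, float]:
    """Height ``(h1, h2)`` at which the ``max`` or ``min`` of the
    through-thickness oxygen profile at the slice centre equals ``value``
    [mmHg].

    The centre line ``r = 0`` is the least oxygenated radius, so its
    extrema are what the physiological-window placement targets (maximum
    65 mmHg at the top face, minimum 35 mmHg in the interior).
    Exploits the monotone dependence of both extrema on the slice height:
    the extremum as a function of ``h1`` is bracketed over the admissible
    range ``[0, H - thickness - 1 um]`` and the root polished by bisection
    (Brent) to ``h_tol`` in ``h1``; the achieved extremum is verified to
    within ``phi_tol`` [mmHg].
    """
    if target not in ("max", "min"):
        raise ValueError("target must be 'max' or 'min'")
    system0, transport = default_parameters(slice_diameter=2 * slice_radius)
    surface = SurfaceOxygen.from_fraction(oxygen_fraction)
    H = system0.media_depth
    t = system0.thickness
    h1_hi = H - t - TOP_CLEARANCE

    def extremum(h1: float) -> float:
        sysg = system0.with_placement(h1)
        sol = solve_oxygen_field(sysg, transport, surface, M=M)
        ext = centreline_extrema(sol)
        return ext.phi_max if target == "max" else ext.phi_min

    lo, hi = extremum(0.0), extremum(h1_hi)
    v_lo, v_hi = min(lo, hi), max(lo, hi)
    if not v_lo <= value <= v_hi:
        raise UnattainableTargetError(
            f"target {target}={value} mmHg outside the attainable range "
            f"[{v_lo:.4f}, {v_hi:.4f}] mmHg for this scenario"
        )
    h1 = brentq(lambda h: extremum(h) - value, 0.0, h1_hi, xtol=h_tol, maxiter=200)
    achieved = extremum(h1)
    if abs(achieved - value) > phi_tol:
        raise RuntimeError(
            f"placement search converged in h1 but extremum {achieved:.4f} is "
            f"{abs(achieved - value):.4f} mmHg from the target"
        )
    return float(h1), float(h1 + t)


def depth_sweep(
    slice_radius: float = 2.5e-3,
    oxygen_fraction: float = 0.21,
    n_steps: int = 25,
    M: int = 7,
    scope: str = "centre",
) -> pd.DataFrame:
    """Tissue extrema as the slice descends from just below the surface to
    the well bottom.  Columns: h1_mm, phi_min_mmHg, phi_max_mmHg.

    ``scope`` selects centre-line extrema (default, the published
    depth-sensitivity quantity) or tissue-wide grid extrema."""
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    system0, transport = default_parameters(slice_diameter=2 * slice_radius)
    surface = SurfaceOxygen.from_fraction(oxygen_fraction)
    h1_top = system0.media_depth - system0.thickness - TOP_CLEARANCE
    rows = []
    for h1 in np.linspace(h1_top, 0.0, n_steps):
        sol = solve_oxygen_field(system0.with_placement(float(h1)), transport,
                                 surface, M=M)
        ext = tissue_extrema(sol, scope=scope)
        rows.append({"h1_mm": h1 * 1e3, "phi_min_mmHg": ext.phi_min,
                     "phi_max_mmHg": ext.phi_max})
    return pd.DataFrame(rows)


def volume_sweep(
    volumes_ml,
    slice_radius: float = 2.5e-3,
    oxygen_fraction: float = 0.21,
    M: int = 7,
) -> pd.DataFrame:
    """Minimum tissue oxygen as a function of media volume, the slice riding
    one micron below the surface.  Columns: volume_ml, media_depth_mm,
    phi_min_mmHg.

    The minimum is attained on the centre line by symmetry, so the
    centre-line and tissue-wide definitions coincide here."""
    system0, transport = default_parameters(slice_diameter=2 * slice_radius)
    surface = SurfaceOxygen.from_fraction(oxygen_fraction)
    rows = []
    for v_ml in volumes_ml:
        if v_ml <= 0.0:
            raise InvalidGeometryError(f"media volume must be positive, got {v_ml} ml")
        vol = v_ml * 1e-6
        H = media_depth_from_volume(vol, system0.well_radius)
        if H <= system0.thickness + TOP_CLEARANCE:
            raise InvalidGeometryError(
                f"{v_ml} ml gives media depth {H * 1e3:.3f} mm, too shallow for the slice"
            )
        sysg = system0.with_media_depth(H, media_volume=vol)
        sol = solve_oxygen_field(sysg, transport, surface, M=M)
        ext = centreline_extrema(sol)
        rows.append({"volume_ml": v_ml, "media_depth_mm": H * 1e3,
                     "phi_min_mmHg": ext.phi_min})
    return pd.DataFrame(rows)


def run_scenario_grid(M: int = 7) -> list[ScenarioResult]:
    """The full simulated-experiment grid: two slice diameters (5 and 8 mm)
    at 21/80/95% incubator oxygen, each at the three standard placements."""
    results = []
    for d in SLICE_DIAMETERS:
        for f in OXYGEN_FRACTIONS:
            for placement in PLACEMENTS:
                results.append(solve_scenario(Scenario(d, f, placement, M=M)))
    return results


def grid_summary(results: list[ScenarioResult]) -> pd.DataFrame:
    """Per (diameter, oxygen) summary of the mid-plane concentration span
    across the three placements."""
    rows = []
    for d in sorted({r.scenario.slice_diameter for r in results}):
        for f in sorted({r.scenario.oxygen_fraction for r in results}):
            sel = [r for r in results
                   if r.scenario.slice_diameter == d and r.scenario.oxygen_fraction == f]
            if not sel:
                continue
            values = np.concatenate([r.midplane.phi for r in sel])
            rows.append({
                "slice_diameter_mm": d * 1e3,
                "oxygen_percent": f * 100.0,
                "midplane_min_mmHg": float(values.min()),
                "midplane_max_mmHg": float(values.max()),
            })
    return pd.DataFrame(rows)


def table_placements(M: int = 40) -> pd.DataFrame:
    """Placements that put a slice at the physiological oxygen window, for
    both slice diameters at atmospheric oxygen.

    Columns: slice_diameter_mm, target, value_mmHg, h1_mm, h2_mm.
    """
    rows = []
    for d in SLICE_DIAMETERS:
        for target, value in (("max", PHYSIOLOGICAL_MAX_MMHG),
                              ("min", PHYSIOLOGICAL_MIN_MMHG)):
            h1, h2 = find_placement_height(target, value, slice_radius=d / 2.0, M=M)
            rows.append({
                "slice_diameter_mm": d * 1e3,
                "target": target,
                "value_mmHg": value,
                "h1_mm": h1 * 1e3,
                "h2_mm": h2 * 1e3,
            })
    return pd.DataFrame(rows)
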