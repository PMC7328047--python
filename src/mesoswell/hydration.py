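"""Hydration, osmotic stress, swelling curves and phase maps.

Relative humidity sets the water chemical potential, Δμ_w = RT·ln(RH/100),
and hence the osmotic pressure of the vapour-equilibrated sample,
Π_osm = −Δμ_w/V_w, with V_w the molar volume of water. Π_osm is reported
with the nonnegative sign convention (Π_osm = 0 at RH = 100 and grows as
the sample dries).

A lamellar repeat distance d decomposes into a hydrocarbon slab of fixed
thickness d_l and an aqueous-plus-headgroup layer d_w = d − d_l. Swelling
series d(hydration) are assembled from per-sample measurements, with a
simple per-step plateau detector for the saturation of d_w seen in
bridging-limited systems, and phase calls along a hydration axis are merged
into a phase map of single-phase and coexistence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .indexing import PhaseAssignment

__all__ = [
    "GAS_CONSTANT",
    "WATER_MOLAR_VOLUME",
    "DEFAULT_TEMPERATURE",
    "OsmoticConditions",
    "HydrationPoint",
    "SwellingSeries",
    "PhaseInterval",
    "osmotic_pressure",
    "water_layer",
    "build_swelling_series",
    "build_phase_map",
]

GAS_CONSTANT = 8.31446  # J/(mol K)
WATER_MOLAR_VOLUME = 1.805e-5  # m^3/mol at ambient conditions
DEFAULT_TEMPERATURE = 300.15  # K (27 degC equilibration/measurement temperature)


@dataclass(frozen=True)
class OsmoticConditions:
    """Water chemical potential and osmotic pressure at a given RH and T."""

    RH: float  # percent
    T: float  # kelvin
    V_w: float  # m^3/mol
    R: float  # J/(mol K)
    delta_mu_w: float  # J/mol, <= 0
    Pi_osm: float  # Pa, >= 0


def osmotic_pressure(RH: float, T: float = DEFAULT_TEMPERATURE,
                     V_w: float = WATER_MOLAR_VOLUME) -> OsmoticConditions:
    """Convert relative humidity to osmotic pressure.

    Δμ_w = RT·ln(RH/100) ≤ 0 and Π_osm = −Δμ_w/V_w ≥ 0, zero exactly at
    RH = 100%. RH outside (0, 100] raises ``ValueError``.
    """
    if not 0 < RH <= 100:
        raise ValueError(f"RH must lie in (0, 100], got {RH}")
    if T <= 0:
        raise ValueError("temperature must be positive")
    delta_mu = GAS_CONSTANT * T * np.log(RH / 100.0)
    return OsmoticConditions(
        RH=float(RH), T=float(T), V_w=float(V_w), R=GAS_CONSTANT,
        delta_mu_w=float(delta_mu), Pi_osm=float(-delta_mu / V_w),
    )


def water_layer(d: float, d_l: float) -> float:
    """Aqueous-plus-headgroup layer thickness d_w = d − d_l, in Å.

    The returned d_w contains both the polar headgroup region and the
    interbilayer water; d_l is the hydrocarbon thickness only. A repeat
    distance not exceeding d_l yields a warning (not an error) since it
    indicates an inconsistent decomposition rather than invalid input.
    """
    if d <= 0 or d_l <= 0:
        raise ValueError("d and d_l must be positive")
    if d <= d_l:
        warnings.warn(
            f"repeat distance d={d} A does not exceed hydrocarbon thickness "
            f"d_l={d_l} A; d_w is non-positive", stacklevel=2,
        )
    return d - d_l


@dataclass
class HydrationPoint:
    """One measurement along a hydration axis.

    ``hydration_kind`` tags the axis as total water content (``wt_water``)
    or relative humidity (``rh``); the two are never mixed in one series.
    ``d_w`` is filled in as d − d_l for lamellar points when not given.
    """

    hydration: float
    hydration_kind: str
    d: float
    d_l: float | None = None
    d_w: float | None = None
    phase_assignment: "PhaseAssignment | None" = None
    sample_label: str = ""

    def __post_init__(self) -> None:
        if self.hydration_kind not in ("wt_water", "rh"):
            raise ValueError("hydration_kind must be 'wt_water' or 'rh'")
        if self.d_w is None and self.d_l is not None:
            self.d_w = water_layer(self.d, self.d_l)


@dataclass
class SwellingSeries:
    """Ordered lamellar swelling curve with optional plateau call."""

    points: list[HydrationPoint]
    sample_label: str = ""
    plateau_d: float | None = None
    plateau_onset_hydration: float | None = None
    monotonic: bool = True

    @property
    def hydrations(self) -> np.ndarray:
        return np.array([p.hydration for p in self.points])

    @property
    def d(self) -> np.ndarray:
        return np.array([p.d for p in self.points])


def build_swelling_series(points: Sequence[HydrationPoint], sample_label: str = "",
                          plateau_tolerance: float = 0.02) -> SwellingSeries:
    """Sort points by hydration and detect a swelling plateau.

    The plateau onset is the first point beyond which every subsequent step
    changes d by less than ``plateau_tolerance`` (relative, default 2% per
    step); the plateau must contain at least two points. ``plateau_d`` is
    the mean d over the plateau. Non-monotonic series are flagged, not
    rejected.
    """
    pts = sorted(points, key=lambda p: p.hydration)
    if len(pts) < 2:
        raise ValueError("a swelling series needs at least 2 points")
    kinds = {p.hydration_kind for p in pts}
    if len(kinds) > 1:
        raise ValueError(f"mixed hydration axes in one series: {sorted(kinds)}")
    d = np.array([p.d for p in pts])
    steps_flat = np.abs(np.diff(d)) / d[:-1] < plateau_tolerance
    monotonic = bool(np.all(np.diff(d) >= -plateau_tolerance * d[:-1]))
    plateau_d = onset = None
    for i in range(len(pts) - 1):
        if np.all(steps_flat[i:]):
            plateau_d = float(np.mean(d[i:]))
            onset = float(pts[i].hydration)
            break
    return SwellingSeries(
        points=pts, sample_label=sample_label, plateau_d=plateau_d,
        plateau_onset_hydration=onset, monotonic=monotonic,
    )


@dataclass(frozen=True)
class PhaseInterval:
    """One interval of a phase map along the hydration axis.

    Boundaries between intervals sit midway between the adjacent measured
    points; ``boundary_determined`` is False for such interpolated edges
    (the exact positions of phase boundaries are not measured), True for
    edges coinciding with the extreme observed points.
    """

    label: str
    lower: float
    upper: float
    lower_determined: bool
    upper_determined: bool
    support: tuple[float, ...]  # measured hydrations inside the interval


def _phase_label(assignment) -> str:
    """Canonical phase-call string for a PhaseAssignment or plain string."""
    if isinstance(assignment, str):
        return assignment
    names = []
    for fit in assignment.fits:
        names.append(getattr(fit, "phase_name", type(fit).__name__))
    if not names:
        return "unassigned"
    return "+".join(sorted(names))


def build_phase_map(series: Sequence[tuple[float, object]]) -> list[PhaseInterval]:
    """Merge per-hydration phase calls into ordered phase intervals.

    ``series`` holds (hydration, PhaseAssignment-or-label) pairs. Duplicate
    hydrations with conflicting calls raise ``ValueError``. Intervals
    partition the observed hydration range; boundaries between different
    calls are placed midway between the bracketing measurements and flagged
    as not determined.
    """
    if len(series) < 2:
        raise ValueError("a phase map needs at least 2 assignments")
    labelled = sorted(((float(h), _phase_label(a)) for h, a in series), key=lambda t: t[0])
    seen: dict[float, str] = {}
    for h, lab in labelled:
        if h in seen and seen[h] != lab:
            raise ValueError(f"conflicting phase calls at hydration {h}: {seen[h]} vs {lab}")
        seen[h] = lab
    # collapse exact duplicates
    pts = sorted(seen.items())
    intervals: list[PhaseInterval] = []
    start = pts[0][0]
    start_det = True
    run: list[float] = []
    current = pts[0][1]
    for h, lab in pts:
        if lab != current:
            mid = 0.5 * (run[-1] + h)
            intervals.append(PhaseInterval(current, start, mid, start_det, False, tuple(run)))
            start, start_det, current, run = mid, False, lab, []
        run.append(h)
    intervals.append(PhaseInterval(current, start, run[-1], start_det, True, tuple(run)))
    return intervals
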