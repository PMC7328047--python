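"""Synthetic 1D SAXS patterns of lyotropic lipid mesophases.

Forward model used throughout the test suite: Bragg reflections of a
lamellar (L_α), reversed-hexagonal (H_II) or bicontinuous-cubic (Q) lattice
are placed at

* lamellar:   q_n = n · 2π/d                 (n = 1, 2, 3, …)
* hexagonal:  q_i = r_i · 4π/(√3·a),  r_i ∈ {1, √3, 2, √7, 3}
* cubic:      q_i = r_i · 2π/a,       r_i = √(h²+k²+l²) of the allowed hkl

on top of a power-law background A·q⁻ᵖ + c, with pseudo-Voigt peak shapes
and Poisson-like counting noise (Gaussian, σ = noise_scale·√I). Ground-truth
peak centers travel in the curve metadata so downstream peak finding and
indexing can be scored exactly.

The module also provides the two swelling laws used to emulate hydration
series of a lamellar phase: ideal one-dimensional dilution, d = d_hc/φ_hc,
and a bridging-capped law in which the aqueous separation saturates at
d_w_max (the behaviour expected when an adsorbed polymer tethers adjacent
bilayers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .curves import ScatteringCurve
from .hydration import HydrationPoint, SwellingSeries

__all__ = [
    "HEXAGONAL_RATIOS",
    "CUBIC_RATIO_SETS",
    "PhaseSpec",
    "CurveSpec",
    "SwellingLaw",
    "generate_pattern",
    "compose_coexistence",
    "swelling_repeat_distance",
    "generate_swelling_series",
]

#: Reflection-position ratios of the 2D hexagonal lattice: 1, √3, 2, √7, 3.
HEXAGONAL_RATIOS: tuple[float, ...] = (1.0, math.sqrt(3), 2.0, math.sqrt(7), 3.0)

#: Candidate √(h²+k²+l²) sets for bicontinuous cubic phases. Labels are the
#: conventional space-group names; they are candidate indexings only and are
#: never asserted as an assignment.
CUBIC_RATIO_SETS: dict[str, tuple[float, ...]] = {
    "Pn3m": tuple(math.sqrt(s) for s in (2, 3, 4, 6, 8, 9)),
    "Im3m": tuple(math.sqrt(s) for s in (2, 4, 6, 8, 10)),
    "Ia3d": tuple(math.sqrt(s) for s in (6, 8, 14, 16)),
}


@dataclass
class PhaseSpec:
    """One lattice contributing Bragg peaks to a synthetic pattern.

    ``lattice_parameter`` is the lamellar repeat d, the hexagonal a, or the
    cubic a, in Å. ``relative_amplitudes`` defaults to 1/i² decay with
    reflection index (the intensity fall-off per order is a free parameter
    of the forward model). ``peak_width`` is the FWHM in Å⁻¹.
    """

    phase_type: str
    lattice_parameter: float
    n_orders: int = 3
    relative_amplitudes: Sequence[float] | None = None
    peak_width: float = 0.004
    ratio_set: Sequence[float] | None = None
    amplitude: float = 1000.0
    voigt_eta: float = 0.5  # pseudo-Voigt Lorentzian fraction

    def __post_init__(self) -> None:
        if self.phase_type not in ("lamellar", "hexagonal", "cubic"):
            raise ValueError(f"unknown phase_type {self.phase_type!r}")
        if self.lattice_parameter <= 0:
            raise ValueError("lattice_parameter must be positive")
        if self.n_orders < 1:
            raise ValueError("n_orders must be >= 1")
        if self.peak_width <= 0:
            raise ValueError("peak_width must be positive")
        if self.ratio_set is None:
            if self.phase_type == "lamellar":
                self.ratio_set = tuple(float(n) for n in range(1, self.n_orders + 1))
            elif self.phase_type == "hexagonal":
                self.ratio_set = HEXAGONAL_RATIOS
            else:
                self.ratio_set = CUBIC_RATIO_SETS["Pn3m"]
        ratios = np.asarray(self.ratio_set, float)
        if np.any(ratios <= 0) or np.any(np.diff(ratios) <= 0):
            raise ValueError("ratio_set must be strictly increasing and positive")
        if self.n_orders > len(ratios):
            raise ValueError(
                f"n_orders={self.n_orders} exceeds the {len(ratios)} available ratios"
            )
        if self.relative_amplitudes is None:
            self.relative_amplitudes = tuple(1.0 / (i + 1) ** 2 for i in range(self.n_orders))
        if len(self.relative_amplitudes) != self.n_orders:
            raise ValueError("relative_amplitudes must have n_orders entries")
        if any(a <= 0 for a in self.relative_amplitudes):
            raise ValueError("relative_amplitudes must be positive")

    @property
    def q_unit(self) -> float:
        """q of a hypothetical ratio-1 reflection: 2π/d (lamellar),
        4π/(√3·a) (hexagonal) or 2π/a (cubic)."""
        a = self.lattice_parameter
        if self.phase_type == "lamellar":
            return 2 * math.pi / a
        if self.phase_type == "hexagonal":
            return 4 * math.pi / (math.sqrt(3) * a)
        return 2 * math.pi / a

    @property
    def peak_centers(self) -> np.ndarray:
        """Ground-truth reflection positions in Å⁻¹."""
        return np.asarray(self.ratio_set[: self.n_orders], float) * self.q_unit


@dataclass
class CurveSpec:
    """q grid, background and noise of a synthetic curve.

    Defaults mirror a laboratory SAXS configuration: q from 0.012 to
    0.67 Å⁻¹ on 800 points. Background is A·q⁻ᵖ + c. Noise is Gaussian with
    σ = noise_scale·√I; identical seeds give bitwise-identical curves.
    """

    q_min: float = 0.012
    q_max: float = 0.67
    n_points: int = 800
    background_amplitude: float = 1.0
    background_exponent: float = 2.0
    background_constant: float = 5.0
    noise_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.q_min < self.q_max:
            raise ValueError("need 0 < q_min < q_max")
        if self.n_points < 50:
            raise ValueError("n_points must be >= 50")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")

    @property
    def q(self) -> np.ndarray:
        return np.linspace(self.q_min, self.q_max, self.n_points)

    def background(self, q: np.ndarray) -> np.ndarray:
        return (
            self.background_amplitude * q ** (-self.background_exponent)
            + self.background_constant
        )


def _pseudo_voigt(q: np.ndarray, center: float, fwhm: float, eta: float) -> np.ndarray:
    """Unit-height symmetric peak: eta·Lorentzian + (1−eta)·Gaussian."""
    hwhm = fwhm / 2.0
    lorentz = 1.0 / (1.0 + ((q - center) / hwhm) ** 2)
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    gauss = np.exp(-0.5 * ((q - center) / sigma) ** 2)
    return eta * lorentz + (1.0 - eta) * gauss


def generate_pattern(phase: PhaseSpec | Sequence[PhaseSpec], curve: CurveSpec,
                     label: str = "synthetic") -> ScatteringCurve:
    """Render one (or several superposed) lattices onto a noisy background.

    Raises ``ValueError`` naming the offending reflection if any ground-truth
    peak center falls outside [q_min, q_max].
    """
    phases = [phase] if isinstance(phase, PhaseSpec) else list(phase)
    q = curve.q
    intensity = curve.background(q)
    centers: list[float] = []
    truth: list[dict] = []
    for ph in phases:
        for i, (c, amp) in enumerate(zip(ph.peak_centers, ph.relative_amplitudes)):
            if not curve.q_min <= c <= curve.q_max:
                raise ValueError(
                    f"{ph.phase_type} reflection {i + 1} at q={c:.5f} 1/A lies outside "
                    f"the q grid [{curve.q_min}, {curve.q_max}]"
                )
            intensity = intensity + ph.amplitude * amp * _pseudo_voigt(
                q, c, ph.peak_width, ph.voigt_eta
            )
            centers.append(float(c))
        truth.append(
            {
                "phase_type": ph.phase_type,
                "lattice_parameter": ph.lattice_parameter,
                "peak_centers": [float(c) for c in ph.peak_centers],
            }
        )
    if curve.noise_scale > 0:
        rng = np.random.default_rng(curve.seed)
        intensity = intensity + rng.normal(
            0.0, curve.noise_scale * np.sqrt(np.clip(intensity, 0.0, None))
        )
    intensity = np.clip(intensity, 0.0, None)
    meta = {
        "sample": label,
        "seed": curve.seed,
        "noise_scale": curve.noise_scale,
        "true_peak_centers": sorted(centers),
        "true_phases": truth,
    }
    return ScatteringCurve(q, intensity, meta)


def compose_coexistence(curves: Sequence[ScatteringCurve],
                        weights: Sequence[float] | None = None) -> ScatteringCurve:
    """Pointwise weighted sum of curves on one shared q grid; the union of
    the inputs' ground-truth peak centers is carried in the metadata."""
    curves = list(curves)
    if not curves:
        raise ValueError("compose_coexistence needs at least one curve")
    if weights is None:
        weights = [1.0] * len(curves)
    weights = [float(w) for w in weights]
    if len(weights) != len(curves) or any(w <= 0 for w in weights):
        raise ValueError("weights must be positive, one per curve")
    q0 = curves[0].q
    for c in curves[1:]:
        if c.q.shape != q0.shape or not np.allclose(c.q, q0):
            raise ValueError("curves must share one q grid")
    intensity = sum(w * c.intensity for w, c in zip(weights, curves))
    centers = sorted(
        {float(x) for c in curves for x in c.metadata.get("true_peak_centers", [])}
    )
    phases = [p for c in curves for p in c.metadata.get("true_phases", [])]
    meta = {
        "sample": "+".join(str(c.metadata.get("sample", "?")) for c in curves),
        "true_peak_centers": centers,
        "true_phases": phases,
        "weights": weights,
    }
    return ScatteringCurve(q0, np.asarray(intensity, float), meta)


@dataclass
class SwellingLaw:
    """d(hydration) model for a lamellar phase.

    ``ideal_dilution``: the repeat distance follows one-dimensional dilution,
    d = d_hc/φ_hc, where φ_hc is the hydrocarbon volume fraction computed
    from the water weight fraction assuming unit mass densities for lipid
    and water, with a fraction ``headgroup_volume_fraction_of_lipid`` of the
    lipid volume counted as polar headgroup (hence part of the aqueous slab).

    ``bridging_capped``: same, but the aqueous separation d_w = d − d_hc
    cannot exceed ``d_w_max``, so d plateaus at d_hc + d_w_max.
    """

    law_type: str = "ideal_dilution"
    d_hc: float = 27.1
    headgroup_volume_fraction_of_lipid: float = 0.0
    d_w_max: float | None = None

    def __post_init__(self) -> None:
        if self.law_type not in ("ideal_dilution", "bridging_capped"):
            raise ValueError(f"unknown law_type {self.law_type!r}")
        if self.d_hc <= 0:
            raise ValueError("d_hc must be positive")
        if not 0 <= self.headgroup_volume_fraction_of_lipid < 1:
            raise ValueError("headgroup fraction must lie in [0, 1)")
        if self.law_type == "bridging_capped":
            if self.d_w_max is None or self.d_w_max <= 0:
                raise ValueError("bridging_capped requires d_w_max > 0")


def swelling_repeat_distance(law: SwellingLaw, wt_water: float) -> float:
    """Lamellar repeat d in Å at the given water content (wt%)."""
    if not 0 < wt_water < 100:
        raise ValueError(f"wt% water must lie in (0, 100), got {wt_water}")
    phi_water = wt_water / 100.0
    phi_hc = (1.0 - phi_water) * (1.0 - law.headgroup_volume_fraction_of_lipid)
    d = law.d_hc / phi_hc
    if law.law_type == "bridging_capped":
        d = min(d, law.d_hc + float(law.d_w_max))
    return d


def generate_swelling_series(law: SwellingLaw, hydrations: Sequence[float],
                             sample_label: str = "synthetic-swelling") -> SwellingSeries:
    """Ground-truth swelling series: one lamellar HydrationPoint per water
    content, with d from the law and d_w = d − d_hc."""
    hyd = sorted(float(h) for h in hydrations)
    if len(hyd) < 1:
        raise ValueError("need at least one hydration value")
    points = [
        HydrationPoint(
            hydration=h,
            hydration_kind="wt_water",
            d=swelling_repeat_distance(law, h),
            d_l=law.d_hc,
        )
        for h in hyd
    ]
    return SwellingSeries(points=points, sample_label=sample_label)
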