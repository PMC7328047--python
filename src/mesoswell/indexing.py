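"""Assignment of Bragg peaks to lamellar, hexagonal and cubic lattices.

Lamellar phases diffract at q_n = n·2π/d. Peak positions are validated by
regressing q against the reflection order n; the repeat distance is taken
from the slope, d = 2π/slope, and its uncertainty from the spread of the
per-reflection estimates d_n = n·2π/q_n. Hexagonal (H_II) phases are
assigned by fitting reflections to the ratio sequence 1 : √3 : 2 : √7 : 3
of the first peak, giving the lattice parameter a = 4π/(√3·q₁).
Bicontinuous cubic phases are matched against √(h²+k²+l²) candidate sets
for common space groups; because powder patterns of this kind rarely pin
the space group down, cubic results are ranked candidates, never asserted
assignments.

:func:`classify_phase` tries all lattice types on a peak list, ranks fits
by the number of matched reflections, residual and model parsimony
(lamellar < hexagonal < cubic), and — when peaks remain and coexistence is
allowed — fits a second lattice to the leftovers, yielding the two-phase
assignments seen in partially dehydrated samples (e.g. L_α/H_II).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .peaks import PeakList
from .synthetic import CUBIC_RATIO_SETS, HEXAGONAL_RATIOS

__all__ = [
    "LamellarFit",
    "HexagonalFit",
    "CubicCandidate",
    "PhaseAssignment",
    "index_lamellar",
    "index_ratio_lattice",
    "rank_cubic_candidates",
    "classify_phase",
]

_COMPLEXITY = {"lamellar": 0, "hexagonal": 1, "cubic": 2}


@dataclass
class LamellarFit:
    """d-spacing from the order-vs-q regression of a 1D lattice."""

    d: float  # A, = 2 pi / slope
    d_uncertainty: float  # A, sample std of per-reflection d
    assigned_orders: tuple[int, ...]
    slope: float  # 1/A per order
    intercept: float  # 1/A
    per_reflection_d: tuple[float, ...]
    residual_rms: float  # 1/A
    relative_residual_rms: float = 0.0  # dimensionless, used for ranking
    matched_indices: tuple[int, ...] = ()
    misindexing_warning: bool = False
    phase_name: str = "lamellar"

    @property
    def n_matched(self) -> int:
        return len(self.assigned_orders)

    @property
    def lattice_parameter(self) -> float:
        return self.d


@dataclass
class HexagonalFit:
    """2D hexagonal lattice: a = 4π/(√3·q₁)."""

    a: float  # A
    q1: float  # 1/A, fitted first-reflection position
    matched_ratios: tuple[float, ...]
    residual_rms: float  # relative, dimensionless
    matched_indices: tuple[int, ...] = ()
    phase_name: str = "hexagonal"

    @property
    def n_matched(self) -> int:
        return len(self.matched_ratios)

    @property
    def lattice_parameter(self) -> float:
        return self.a


@dataclass
class CubicCandidate:
    """One candidate cubic indexing; a label, never a proven space group."""

    space_group_label: str
    ratio_set: tuple[float, ...]
    a: float  # A
    n_matched: int
    residual_rms: float  # relative, dimensionless
    matched_ratios: tuple[float, ...] = ()
    matched_indices: tuple[int, ...] = ()
    phase_name: str = "cubic"

    @property
    def lattice_parameter(self) -> float:
        return self.a


@dataclass
class PhaseAssignment:
    """Best single- or two-phase explanation of a peak list.

    Every input peak belongs to exactly one fit's ``matched_indices`` or to
    ``unassigned_peaks``. ``cubic_candidates`` carries the full ranked list
    whenever a cubic lattice was competitive.
    """

    fits: list = field(default_factory=list)
    unassigned_peaks: PeakList = field(default_factory=PeakList)
    coexistence: bool = False
    cubic_candidates: list[CubicCandidate] = field(default_factory=list)

    @property
    def phase_names(self) -> tuple[str, ...]:
        return tuple(f.phase_name for f in self.fits)


def _fit_lamellar_subset(q: np.ndarray, indices: Sequence[int], orders: Sequence[int],
                         force_origin: bool = False,
                         uncertainty: str = "std") -> LamellarFit:
    n = np.asarray(orders, float)
    qs = q[list(indices)]
    if force_origin:
        slope = float(np.sum(n * qs) / np.sum(n * n))
        intercept = 0.0
    else:
        if len(qs) == 2 and n[0] == n[1]:
            raise ValueError("degenerate orders")
        slope, intercept = (np.polyfit(n, qs, 1) if len(qs) > 1 else (qs[0] / n[0], 0.0))
        slope, intercept = float(slope), float(intercept)
    resid = qs - (slope * n + intercept)
    per_d = 2.0 * math.pi * n / qs
    if uncertainty == "sem":
        unc = float(np.std(per_d, ddof=1) / math.sqrt(len(per_d))) if len(per_d) > 1 else 0.0
    else:
        unc = float(np.std(per_d, ddof=1)) if len(per_d) > 1 else 0.0
    rms = float(np.sqrt(np.mean(resid**2)))
    rel_rms = float(np.sqrt(np.mean((resid / qs) ** 2)))
    return LamellarFit(
        d=2.0 * math.pi / slope,
        d_uncertainty=unc,
        assigned_orders=tuple(int(x) for x in orders),
        slope=slope,
        intercept=intercept,
        per_reflection_d=tuple(float(x) for x in per_d),
        residual_rms=rms,
        relative_residual_rms=rel_rms,
        matched_indices=tuple(int(i) for i in indices),
        misindexing_warning=bool(abs(intercept) > 3.0 * rms) if rms > 0 else False,
    )


def _match_orders(q: np.ndarray, q1: float, tolerance_rel: float):
    """Greedy assignment of peaks to integer orders of q1; one peak per
    order (the closer wins)."""
    matched: dict[int, int] = {}  # order -> peak index
    for i, qi in enumerate(q):
        n = int(round(qi / q1))
        if n < 1:
            continue
        if abs(qi - n * q1) / qi > tolerance_rel:
            continue
        if n in matched:
            if abs(q[matched[n]] - n * q1) <= abs(qi - n * q1):
                continue
        matched[n] = i
    orders = sorted(matched)
    return [matched[n] for n in orders], orders


def index_lamellar(peaks: PeakList, tolerance_rel: float = 0.01,
                   force_origin: bool = False,
                   uncertainty: str = "std") -> LamellarFit | None:
    """Index a peak list as a single lamellar lattice.

    Orders are assigned as nearest integers to q_i/q_first (gaps allowed),
    a straight line q = slope·n + intercept is fitted, and d = 2π/slope.
    ``d_uncertainty`` is the sample standard deviation of the
    per-reflection d_n = 2πn/q_n (``uncertainty='sem'`` switches to the
    standard error). Returns ``None`` (no fit) if fewer than two peaks
    match or any matched peak misses its predicted position by more than
    ``tolerance_rel`` (relative); a significant intercept only raises the
    ``misindexing_warning`` flag.
    """
    if len(peaks) < 2:
        return None
    q = peaks.q
    indices, orders = _match_orders(q, q[0], tolerance_rel)
    if len(indices) < 2:
        return None
    fit = _fit_lamellar_subset(q, indices, orders, force_origin, uncertainty)
    pred = fit.slope * np.asarray(orders, float) + fit.intercept
    if np.any(np.abs(q[indices] - pred) / q[indices] > tolerance_rel):
        return None
    if len(indices) < len(peaks):
        return None  # spec contract: a pure-lamellar call must explain all peaks
    return fit


def _match_ratios(q: np.ndarray, q_unit: float, ratio_set: Sequence[float],
                  tolerance_rel: float):
    """Greedy peak→ratio matching at a fixed q_unit; each ratio used once."""
    matched: dict[int, int] = {}  # ratio index -> peak index
    ratios = np.asarray(ratio_set, float)
    for i, qi in enumerate(q):
        j = int(np.argmin(np.abs(ratios * q_unit - qi)))
        if abs(qi - ratios[j] * q_unit) / qi > tolerance_rel:
            continue
        if j in matched:
            if abs(q[matched[j]] - ratios[j] * q_unit) <= abs(qi - ratios[j] * q_unit):
                continue
        matched[j] = i
    order = sorted(matched)
    return [matched[j] for j in order], [float(ratios[j]) for j in order]


def _fit_ratio_lattice(q: np.ndarray, ratio_set: Sequence[float], tolerance_rel: float,
                       lattice: str, label: str = "",
                       anchor_indices: Sequence[int] | None = None):
    """Best ratio-set fit over all (peak, ratio) anchor hypotheses."""
    ratios = np.asarray(ratio_set, float)
    best = None
    anchors = anchor_indices if anchor_indices is not None else range(len(q))
    for i in anchors:
        for r in ratios:
            q_unit0 = q[i] / r
            idx, matched = _match_ratios(q, q_unit0, ratios, tolerance_rel)
            if len(idx) < 2:
                continue
            rr = np.asarray(matched)
            qs = q[idx]
            q_unit = float(np.sum(rr * qs) / np.sum(rr * rr))  # least squares
            idx, matched = _match_ratios(q, q_unit, ratios, tolerance_rel)
            if len(idx) < 2:
                continue
            rr, qs = np.asarray(matched), q[idx]
            q_unit = float(np.sum(rr * qs) / np.sum(rr * rr))
            resid = (qs - rr * q_unit) / qs
            rms = float(np.sqrt(np.mean(resid**2)))
            key = (len(idx), -rms)
            if best is None or key > best[0]:
                best = (key, idx, matched, q_unit, rms)
    if best is None:
        return None
    _, idx, matched, q_unit, rms = best
    if lattice == "hexagonal":
        return HexagonalFit(
            a=4.0 * math.pi / (math.sqrt(3.0) * q_unit),
            q1=q_unit,
            matched_ratios=tuple(matched),
            residual_rms=rms,
            matched_indices=tuple(int(i) for i in idx),
        )
    return CubicCandidate(
        space_group_label=label,
        ratio_set=tuple(float(r) for r in ratios),
        a=2.0 * math.pi / q_unit,
        n_matched=len(idx),
        residual_rms=rms,
        matched_ratios=tuple(matched),
        matched_indices=tuple(int(i) for i in idx),
    )


def index_ratio_lattice(peaks: PeakList, ratio_set: Sequence[float] = HEXAGONAL_RATIOS,
                        tolerance_rel: float = 0.01, lattice: str = "hexagonal",
                        label: str = "") -> HexagonalFit | CubicCandidate | None:
    """Fit peaks to a fixed reflection-ratio sequence.

    The unit spacing q₁ is estimated by least squares over all peaks that
    match a ratio within ``tolerance_rel``; for hexagonal lattices
    a = 4π/(√3·q₁), for cubic sets (ratios √(h²+k²+l²)) a = 2π/q_unit.
    Fewer than two matched ratios → ``None``.
    """
    if len(peaks) < 2:
        return None
    return _fit_ratio_lattice(peaks.q, ratio_set, tolerance_rel, lattice, label)


def rank_cubic_candidates(peaks: PeakList, tolerance_rel: float = 0.01,
                          ratio_sets: dict[str, Sequence[float]] | None = None,
                          min_matched: int = 3) -> list[CubicCandidate]:
    """All cubic candidate indexings with ≥ ``min_matched`` reflections,
    best (most matches, lowest residual) first."""
    sets = ratio_sets if ratio_sets is not None else CUBIC_RATIO_SETS
    out = []
    for name, ratios in sets.items():
        fit = index_ratio_lattice(peaks, ratios, tolerance_rel, "cubic", name)
        if fit is not None and fit.n_matched >= min_matched:
            out.append(fit)
    out.sort(key=lambda f: (-f.n_matched, f.residual_rms))
    return out


def _best_lamellar_subset(peaks: PeakList, tolerance_rel: float) -> LamellarFit | None:
    """Best partial lamellar fit: every peak is tried as the fundamental."""
    q = peaks.q
    best = None
    for i in range(len(q)):
        indices, orders = _match_orders(q, q[i], tolerance_rel)
        if len(indices) < 2:
            continue
        try:
            fit = _fit_lamellar_subset(q, indices, orders)
        except ValueError:
            continue
        pred = fit.slope * np.asarray(orders, float) + fit.intercept
        ok = np.abs(q[indices] - pred) / q[indices] <= tolerance_rel
        if not np.all(ok):
            continue
        key = (fit.n_matched, -fit.residual_rms)
        if best is None or key > (best.n_matched, -best.residual_rms):
            best = fit
    return best


def _candidate_fits(peaks: PeakList, tolerance_rel: float,
                    cubic_sets: dict[str, Sequence[float]],
                    significance_rel: float = 0.1):
    fits = []
    lam = _best_lamellar_subset(peaks, tolerance_rel)
    if lam is not None:
        fits.append(lam)
    hexa = index_ratio_lattice(peaks, HEXAGONAL_RATIOS, tolerance_rel, "hexagonal")
    if hexa is not None:
        fits.append(hexa)
    cubics = rank_cubic_candidates(peaks, tolerance_rel, cubic_sets)
    fits.extend(cubics)
    # Rank on matched significant peaks first (prominence >= significance_rel
    # of the strongest) so a lattice cannot win by sweeping up borderline
    # noise bumps, then on total matches, then parsimony
    # (lamellar < hexagonal < cubic): 1, 2, 3 is also a subset of the
    # hexagonal ratio sequence, and residual jitter must not flip that call.
    # All candidates already satisfy the match tolerance, so the residual
    # only settles exact ties.
    proms = np.array([p.prominence for p in peaks.peaks])
    sig = set(np.nonzero(proms >= significance_rel * proms.max())[0]) if proms.size else set()
    fits.sort(
        key=lambda f: (
            -len(sig & set(f.matched_indices)),
            -f.n_matched,
            _COMPLEXITY[f.phase_name],
            getattr(f, "relative_residual_rms", f.residual_rms),
        )
    )
    return fits, cubics


def classify_phase(peaks: PeakList, allow_coexistence: bool = True,
                   tolerance_rel: float = 0.01,
                   cubic_sets: dict[str, Sequence[float]] | None = None) -> PhaseAssignment:
    """Best single- or two-phase lattice assignment of a peak list.

    All lattice types are fitted; candidates are ranked by matched-peak
    count, then residual, then parsimony (lamellar before hexagonal before
    cubic). If unexplained peaks remain and ``allow_coexistence`` is true, a
    second lattice is fitted greedily to the residual peaks. Peaks matched
    by neither fit are returned in ``unassigned_peaks``.
    """
    if len(peaks) == 0:
        raise ValueError("classify_phase needs a nonempty PeakList")
    sets = cubic_sets if cubic_sets is not None else CUBIC_RATIO_SETS
    fits, cubics = _candidate_fits(peaks, tolerance_rel, sets)
    if not fits:
        return PhaseAssignment(fits=[], unassigned_peaks=peaks, coexistence=False)
    primary = fits[0]
    assigned = set(primary.matched_indices)
    remaining = [i for i in range(len(peaks)) if i not in assigned]
    chosen = [primary]
    all_cubics = list(cubics)
    if remaining and allow_coexistence and len(remaining) >= 2:
        rest = peaks.subset(remaining)
        second_fits, second_cubics = _candidate_fits(rest, tolerance_rel, sets)
        all_cubics.extend(second_cubics)
        if second_fits:
            second = second_fits[0]
            # translate subset indices back to the original peak list
            second.matched_indices = tuple(remaining[i] for i in second.matched_indices)
            chosen.append(second)
            assigned |= set(second.matched_indices)
            remaining = [i for i in range(len(peaks)) if i not in assigned]
    unassigned = peaks.subset(remaining)
    return PhaseAssignment(
        fits=chosen,
        unassigned_peaks=unassigned,
        coexistence=len(chosen) > 1,
        cubic_candidates=all_cubics,
    )
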