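"""Background handling and Bragg-peak location in 1D scattering curves.

The diffuse background of an integrated SAXS curve is modelled as a
power law plus constant, A·q⁻ᵖ + c, fitted robustly with iterative
rejection of points sitting above the running fit (i.e. the peaks), then
subtracted. Peak maxima are located with :func:`scipy.signal.find_peaks`
after light Savitzky–Golay smoothing, filtered on relative prominence and
minimum separation, and each center is refined by a parabola through the
three samples around the maximum — sub-grid precision that plain argmax
cannot give.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal

from .curves import ScatteringCurve

__all__ = ["Peak", "PeakList", "subtract_background", "find_peaks"]


@dataclass(frozen=True)
class Peak:
    q_center: float  # 1/A
    height: float  # a.u.
    prominence: float  # a.u.
    width: float  # FWHM, 1/A


@dataclass
class PeakList:
    """Detected Bragg peaks, ordered by increasing q."""

    peaks: list[Peak] = field(default_factory=list)
    source_label: str = ""

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.q_center)
        q = self.q
        if q.size and np.any(np.diff(q) <= 0):
            raise ValueError("peak centers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def q(self) -> np.ndarray:
        return np.array([p.q_center for p in self.peaks])

    @property
    def heights(self) -> np.ndarray:
        return np.array([p.height for p in self.peaks])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "q": [p.q_center for p in self.peaks],
                "height": [p.height for p in self.peaks],
                "prominence": [p.prominence for p in self.peaks],
                "width": [p.width for p in self.peaks],
            }
        )

    @classmethod
    def from_frame(cls, df, source_label: str = "") -> "PeakList":
        cols = {c.lower(): c for c in df.columns}
        peaks = [
            Peak(
                float(row[cols["q"]]),
                float(row[cols.get("height", cols["q"])]),
                float(row.get(cols.get("prominence", ""), 0.0) or 0.0),
                float(row.get(cols.get("width", ""), 0.0) or 0.0),
            )
            for _, row in df.iterrows()
        ]
        return cls(peaks=peaks, source_label=source_label)

    def subset(self, indices) -> "PeakList":
        return PeakList([self.peaks[i] for i in indices], self.source_label)


def _power_law(q, amplitude, exponent, constant):
    return amplitude * q ** (-exponent) + constant


def subtract_background(curve: ScatteringCurve, n_iter: int = 5,
                        reject_z: float = 3.0) -> ScatteringCurve:
    """Fit A·q⁻ᵖ + c to the peak-free part of the curve and subtract it.

    The fit is weighted by counting statistics (σ ∝ √I, so the decades-
    spanning low-q region is fitted in relative rather than absolute terms)
    and iterated, each round excluding points whose standardized residual
    (I − model)/√model exceeds ``reject_z`` — Bragg peaks stand many σ
    above the background and drop out of the fit support after the first
    round, while the symmetric noise of peak-free regions is retained. The
    subtracted curve may contain small negatives;
    ``metadata['background_negative']`` flags them. If the fit fails the
    input is returned unchanged with ``metadata['background_warning']``
    set.
    """
    q, inten = curve.q, curve.intensity
    if np.allclose(inten, 0.0):
        return curve.copy_with(inten.copy(), background_params=(0.0, 0.0, 0.0),
                               background_negative=False)
    mask = np.ones(inten.size, bool)
    params = None
    p0 = (max(inten.min() * q.min() ** 2, 1e-12), 2.0, max(float(np.median(inten)), 0.0))
    for _ in range(n_iter):
        try:
            weights = np.sqrt(np.clip(inten[mask], 1.0, None))
            params, _ = optimize.curve_fit(
                _power_law, q[mask], inten[mask], p0=p0, sigma=weights,
                bounds=([0.0, 0.0, 0.0], [np.inf, 6.0, np.inf]), maxfev=5000,
            )
        except (RuntimeError, ValueError):
            break
        p0 = tuple(params)
        model = _power_law(q, *params)
        z = (inten - model) / np.sqrt(np.clip(model, 1.0, None))
        new_mask = z < reject_z
        if new_mask.sum() < 10 or np.array_equal(new_mask, mask):
            mask = new_mask if new_mask.sum() >= 10 else mask
            break
        mask = new_mask
    if params is None:
        warnings.warn("background fit failed; returning curve unchanged", stacklevel=2)
        return curve.copy_with(inten.copy(), background_warning=True)
    residual = inten - _power_law(q, *params)
    return curve.copy_with(
        residual,
        background_params=tuple(float(p) for p in params),
        background_negative=bool(np.any(residual < 0)),
    )


def _parabolic_refine(q: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through (q, y) at i-1, i, i+1; falls back to
    the grid point at the array edges or for degenerate curvature."""
    if i == 0 or i == len(y) - 1:
        return float(q[i]), float(y[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom >= 0:  # not a local max in the quadratic sense
        return float(q[i]), float(y[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    dq = 0.5 * (q[i + 1] - q[i - 1])
    height = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta
    return float(q[i] + delta * dq), float(height)


def _local_noise_sigma(raw: np.ndarray, smoothed: np.ndarray,
                       window: int = 31) -> np.ndarray:
    """Pointwise noise scale from the high-frequency residual raw−smoothed,
    as a rolling median absolute deviation (noise in counting data grows
    with intensity, so a global estimate would be wrong at low q)."""
    detail = np.abs(raw - smoothed)
    return 1.4826 * ndimage.median_filter(detail, size=min(window, detail.size))


def find_peaks(curve: ScatteringCurve, min_prominence_rel: float = 0.02,
               min_separation: float = 0.005, smooth: bool = True,
               refine: bool = True, noise_significance: float = 5.0) -> PeakList:
    """Locate Bragg peaks in a (background-subtracted) curve.

    Local maxima are kept when their prominence is at least
    ``min_prominence_rel`` times the largest prominence in the curve, at
    least ``noise_significance`` times the local noise scale (so noise
    spikes riding the steep low-q background are not promoted to peaks),
    and maxima are at least ``min_separation`` (Å⁻¹) apart. Centers are
    refined by three-point parabolic interpolation unless ``refine`` is
    False. An empty :class:`PeakList` — not an error — is returned when
    nothing qualifies.
    """
    raw = curve.intensity.astype(float)
    y = raw
    if smooth and y.size >= 5:
        y = signal.savgol_filter(y, window_length=5, polyorder=2)
    y_pos = np.clip(y, 0.0, None)  # prominence on clipped data only
    if not np.any(y_pos > 0):
        return PeakList(source_label=str(curve.metadata.get("sample", "")))
    dq = curve.dq or 1.0
    distance = max(1, int(round(min_separation / dq)))
    idx, props = signal.find_peaks(y_pos, prominence=1e-12, distance=distance)
    if idx.size == 0:
        return PeakList(source_label=str(curve.metadata.get("sample", "")))
    prominences = props["prominences"]
    keep = prominences >= min_prominence_rel * prominences.max()
    if noise_significance > 0 and y.size >= 5:
        sigma = _local_noise_sigma(raw, y)
        keep &= prominences >= noise_significance * sigma[idx]
    idx, prominences = idx[keep], prominences[keep]
    if idx.size == 0:
        return PeakList(source_label=str(curve.metadata.get("sample", "")))
    widths = signal.peak_widths(y_pos, idx, rel_height=0.5)[0] * dq
    peaks = []
    for i, prom, w in zip(idx, prominences, widths):
        if refine:
            qc, h = _parabolic_refine(curve.q, y, int(i))
        else:
            qc, h = float(curve.q[i]), float(y[i])
        peaks.append(Peak(q_center=qc, height=h, prominence=float(prom), width=float(w)))
    return PeakList(peaks=peaks, source_label=str(curve.metadata.get("sample", "")))
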