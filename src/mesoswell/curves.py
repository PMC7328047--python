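"""1D scattering-curve container and plain-text I/O.

A :class:`ScatteringCurve` is the pipeline's primary input: an azimuthally
integrated intensity profile I(q) with q in inverse Ångström, plus free-form
metadata (sample label, hydration, temperature, and — for synthetic curves —
ground-truth peak positions).

Curves are exchanged as two-column ASCII (``#``-prefixed comment header,
columns q and intensity) or as CSV with ``q,intensity`` headers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["ScatteringCurve", "read_curve", "write_curve"]


@dataclass
class ScatteringCurve:
    """Intensity versus scattering-vector magnitude.

    Parameters
    ----------
    q : array
        Scattering vector magnitudes in Å⁻¹, strictly increasing.
    intensity : array
        Intensities in arbitrary units, same length as ``q``, finite.
        May contain small negatives after background subtraction.
    metadata : dict
        Sample label, hydration (``hydration`` + ``hydration_kind`` of
        ``wt_water`` or ``rh``), temperature in K, and any provenance keys.
    """

    q: np.ndarray
    intensity: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must be 1D arrays of equal length")
        if self.q.size and np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return self.q.size

    @property
    def dq(self) -> float:
        """Median grid spacing in Å⁻¹."""
        return float(np.median(np.diff(self.q))) if self.q.size > 1 else 0.0

    def copy_with(self, intensity: np.ndarray, **meta: Any) -> "ScatteringCurve":
        md = dict(self.metadata)
        md.update(meta)
        return ScatteringCurve(self.q.copy(), np.asarray(intensity, float), md)


def _json_safe(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_curve(path: str | Path, curve: ScatteringCurve, sidecar: bool = False) -> Path:
    """Write a curve as two-column ASCII (``.dat``/``.txt``) or CSV (``.csv``).

    With ``sidecar=True`` the metadata (including any ground-truth peak
    centers) is written next to the curve as ``<stem>.json``.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        pd.DataFrame({"q": curve.q, "intensity": curve.intensity}).to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            for key, val in curve.metadata.items():
                if np.isscalar(val) or isinstance(val, str):
                    fh.write(f"# {key}: {val}\n")
            fh.write("# columns: q[1/A] intensity[a.u.]\n")
            for qi, ii in zip(curve.q, curve.intensity):
                fh.write(f"{qi:.8g} {ii:.8g}\n")
    if sidecar:
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(_json_safe(curve.metadata), fh, indent=2)
    return path


def read_curve(path: str | Path, **metadata: Any) -> ScatteringCurve:
    """Read a two-column ASCII or CSV curve; a ``<stem>.json`` sidecar, if
    present, is merged into the metadata."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        cols = {c.lower().strip(): c for c in df.columns}
        if "q" not in cols:
            raise ValueError(f"{path}: CSV curve needs a 'q' column")
        icol = cols.get("intensity") or cols.get("i")
        if icol is None:
            raise ValueError(f"{path}: CSV curve needs an 'intensity' column")
        q, inten = df[cols["q"]].to_numpy(float), df[icol].to_numpy(float)
        md: dict[str, Any] = {}
    else:
        md = {}
        rows: list[tuple[float, float]] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line.lstrip("#").strip()
                    if ":" in body:
                        key, _, val = body.partition(":")
                        md[key.strip()] = val.strip()
                    continue
                parts = line.replace(",", " ").split()
                if len(parts) < 2:
                    raise ValueError(f"{path}: malformed data line {line!r}")
                rows.append((float(parts[0]), float(parts[1])))
        if not rows:
            raise ValueError(f"{path}: no data rows")
        arr = np.array(rows)
        q, inten = arr[:, 0], arr[:, 1]
    sidecar = path.with_suffix(".json")
    if sidecar.exists() and sidecar != path:
        with open(sidecar) as fh:
            md.update(json.load(fh))
    md.update(metadata)
    md.setdefault("source_path", str(path))
    return ScatteringCurve(q, inten, md)
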