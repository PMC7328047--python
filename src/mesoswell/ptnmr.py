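"""Per-carbon mobility comparison from polarization-transfer ssNMR intensities.

Cross-polarization (CP) favours rigid, ordered C–H bonds, refocused INEPT
favours mobile ones, and direct polarization (DP) involves no transfer and
serves as the reference. Intensity ratios r_CP = I_CP/I_DP and
r_INEPT = I_INEPT/I_DP per carbon therefore report qualitatively on
segmental mobility — they are not quantitative order parameters, so this
module only assigns coarse regimes (mobile / rigid / intermediate /
undetected) and flags carbons whose rINEPT ratio drops between two samples
(e.g. on protein binding) by more than a threshold fraction.

Input is a per-carbon peak-intensity table (CSV columns: carbon, cp, dp,
inept) on a shared acquisition scaling; raw spectra are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CarbonPeakTable",
    "MobilityReport",
    "read_peak_table",
    "normalize_ratios",
    "compare_samples",
]


@dataclass
class CarbonPeakTable:
    """CP/DP/rINEPT intensities per carbon, one sample."""

    table: pd.DataFrame  # columns: carbon, cp, dp, inept
    sample_label: str = ""

    def __post_init__(self) -> None:
        cols = {c.lower(): c for c in self.table.columns}
        missing = [c for c in ("carbon", "cp", "dp", "inept") if c not in cols]
        if missing:
            raise ValueError(f"peak table missing columns: {missing}")
        df = self.table.rename(columns={cols[k]: k for k in ("carbon", "cp", "dp", "inept")})
        df = df[["carbon", "cp", "dp", "inept"]].copy()
        for c in ("cp", "dp", "inept"):
            df[c] = df[c].astype(float)
            if (df[c] < 0).any():
                raise ValueError(f"negative {c.upper()} intensity")
        if df["carbon"].duplicated().any():
            raise ValueError("duplicate carbon labels")
        self.table = df.reset_index(drop=True)


@dataclass
class MobilityReport:
    """Per-carbon ratios, regimes and (for comparisons) flags."""

    table: pd.DataFrame
    sample_label: str = ""
    unshared: dict[str, list[str]] = field(default_factory=dict)


def read_peak_table(path: str | Path, sample_label: str | None = None) -> CarbonPeakTable:
    path = Path(path)
    return CarbonPeakTable(pd.read_csv(path), sample_label or path.stem)


def normalize_ratios(table: CarbonPeakTable, m_thresh: float = 0.3,
                     c_thresh: float = 0.3, floor: float = 0.05) -> MobilityReport:
    """Compute r_CP and r_INEPT per carbon and assign a mobility regime.

    mobile: r_INEPT ≥ ``m_thresh`` and r_INEPT > r_CP; rigid: r_CP ≥
    ``c_thresh`` with r_INEPT below the detection ``floor``; undetected:
    all three intensities below the floor (relative to the strongest DP
    signal); intermediate otherwise. Rows with DP = 0 but detectable CP or
    INEPT cannot be normalised and are dropped with a warning.
    """
    df = table.table.copy()
    ref = df["dp"].max()
    detect = floor * ref if ref > 0 else 0.0
    rows = []
    for _, row in df.iterrows():
        if row["cp"] <= detect and row["dp"] <= detect and row["inept"] <= detect:
            rows.append((row["carbon"], np.nan, np.nan, "undetected"))
            continue
        if row["dp"] <= 0:
            warnings.warn(
                f"carbon {row['carbon']}: DP intensity is zero, row dropped",
                stacklevel=2,
            )
            continue
        r_cp = row["cp"] / row["dp"]
        r_inept = row["inept"] / row["dp"]
        if r_inept >= m_thresh and r_inept > r_cp:
            regime = "mobile"
        elif r_cp >= c_thresh and r_inept < floor:
            regime = "rigid"
        else:
            regime = "intermediate"
        rows.append((row["carbon"], r_cp, r_inept, regime))
    out = pd.DataFrame(rows, columns=["carbon", "r_cp", "r_inept", "regime"])
    return MobilityReport(table=out, sample_label=table.sample_label)


def compare_samples(reference: CarbonPeakTable, treated: CarbonPeakTable,
                    flag_threshold: float = 0.2, **ratio_kwargs) -> MobilityReport:
    """Flag carbons whose rINEPT/DP ratio drops between two samples.

    Δr_INEPT = r_INEPT(treated) − r_INEPT(reference) per shared carbon; a
    carbon is flagged when the relative reduction
    (r_ref − r_treated)/r_ref exceeds ``flag_threshold`` (default 20%).
    Carbons present in only one table are listed in ``unshared``, never
    flagged. No shared carbons at all is an error.
    """
    ref = normalize_ratios(reference, **ratio_kwargs)
    trt = normalize_ratios(treated, **ratio_kwargs)
    merged = ref.table.merge(trt.table, on="carbon", suffixes=("_ref", "_treated"))
    if merged.empty:
        raise ValueError("no shared carbon labels between the two tables")
    merged["delta_r_inept"] = merged["r_inept_treated"] - merged["r_inept_ref"]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = -merged["delta_r_inept"] / merged["r_inept_ref"]
    merged["relative_reduction"] = rel.replace([np.inf, -np.inf], np.nan)
    merged["flagged"] = merged["relative_reduction"] >= flag_threshold
    unshared = {
        ref.sample_label or "reference": sorted(
            set(ref.table["carbon"]) - set(trt.table["carbon"])
        ),
        trt.sample_label or "treated": sorted(
            set(trt.table["carbon"]) - set(ref.table["carbon"])
        ),
    }
    return MobilityReport(
        table=merged,
        sample_label=f"{ref.sample_label} vs {trt.sample_label}",
        unshared=unshared,
    )
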