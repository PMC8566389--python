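"""Per-case feature extraction.

Within the progressive ROI, each of the three quantitative maps (FET-PET
tumor-to-background ratio, rCBV, APTw) contributes eight features: the 5th,
25th, 50th, 75th and 95th percentile intensities, the inter-quartile range,
the Shannon entropy of a 64-bin equal-width histogram, and the hot-spot
volume above a literature threshold (TBR > 2, rCBV > 5.6%, APTw > 1.79%),
for 24 features per case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .roi import ProgressiveROI

MODALITIES = ("tbr", "rcbv", "aptw")
_STAT_NAMES = ("p05", "p25", "p50", "p75", "p95", "iqr", "entropy")

#: Canonical, ordered column names of the 24-feature vector.
FEATURE_COLUMNS = tuple(
    f"{m}_{s}" for m in MODALITIES for s in _STAT_NAMES + ("hotspot_mm3",)
)

__all__ = [
    "ThresholdConfig", "FEATURE_COLUMNS", "MODALITIES",
    "tbr_map", "summary_stats", "hotspot_volume", "assemble_features",
]


@dataclass
class ThresholdConfig:
    """Hot-spot cutoffs (strict '>' — values exactly at a threshold are
    excluded) and histogram settings."""

    aptw_hotspot: float = 1.79   # APTw percentage points
    tbr_hotspot: float = 2.0     # tumor-to-background ratio
    rcbv_hotspot: float = 5.6    # rCBV %
    percentiles: tuple[float, ...] = (5, 25, 50, 75, 95)
    entropy_bins: int = 64

    def __post_init__(self) -> None:
        p = tuple(self.percentiles)
        if list(p) != sorted(p) or not all(0 < q < 100 for q in p):
            raise ValueError("percentiles must be sorted and inside (0, 100)")
        if min(self.aptw_hotspot, self.tbr_hotspot, self.rcbv_hotspot) <= 0:
            raise ValueError("hot-spot thresholds must be positive")
        if self.entropy_bins < 1:
            raise ValueError("entropy_bins must be >= 1")

    def threshold_for(self, modality: str) -> float:
        return {"tbr": self.tbr_hotspot, "rcbv": self.rcbv_hotspot,
                "aptw": self.aptw_hotspot}[modality]


def tbr_map(fet: np.ndarray, background_mask: np.ndarray) -> np.ndarray:
    """Voxelwise tracer activity divided by the mean activity over the
    (tumor-excluded white matter) background mask."""
    fet = np.asarray(fet, dtype=float)
    mask = np.asarray(background_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty background mask")
    bg = float(fet[mask].mean())
    if bg <= 0:
        raise ValueError(f"non-positive background activity ({bg:.3g})")
    return fet / bg


def shannon_entropy(values: np.ndarray, bins: int = 64) -> float:
    """Entropy in bits of an equal-width histogram spanning the values' own
    min-max range; a constant sample has entropy 0 by convention."""
    values = np.asarray(values, dtype=float)
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return 0.0
    counts, _ = np.histogram(values, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / values.size
    return float(-(p * np.log2(p)).sum())


def summary_stats(map_volume: np.ndarray, roi: ProgressiveROI,
                  config: ThresholdConfig | None = None) -> dict[str, float]:
    """The seven intensity statistics over the ROI; raises on an empty ROI
    (callers flag the case instead)."""
    config = config or ThresholdConfig()
    if roi.is_empty:
        raise ValueError("empty ROI: summary statistics undefined")
    vals = np.asarray(map_volume, dtype=float)[roi.mask]
    pcts = np.percentile(vals, config.percentiles)  # linear interpolation
    stats = dict(zip(("p05", "p25", "p50", "p75", "p95"), map(float, pcts)))
    stats["iqr"] = stats["p75"] - stats["p25"]
    stats["entropy"] = shannon_entropy(vals, config.entropy_bins)
    return stats


def hotspot_volume(map_volume: np.ndarray, roi: ProgressiveROI,
                   threshold: float,
                   voxel_volume_mm3: float | None = None) -> float:
    """Volume (mm^3) of ROI voxels whose map value strictly exceeds the
    threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    vv = roi.voxel_volume_mm3 if voxel_volume_mm3 is None else voxel_volume_mm3
    vals = np.asarray(map_volume, dtype=float)[roi.mask]
    return float((vals > threshold).sum()) * vv


def assemble_features(case_id: str, label: str,
                      maps: dict[str, np.ndarray], roi: ProgressiveROI,
                      config: ThresholdConfig | None = None) -> pd.Series:
    """Build the ordered 24-feature row for one case.

    ``maps`` must provide the 'tbr', 'rcbv' and 'aptw' volumes on the ROI's
    grid. An empty ROI yields an all-missing row with ``empty_roi=True``
    so the case is flagged rather than silently dropped.
    """
    config = config or ThresholdConfig()
    row: dict[str, object] = {"case_id": case_id, "label": label}
    if roi.is_empty:
        row.update({c: np.nan for c in FEATURE_COLUMNS})
        row["empty_roi"] = True
        return pd.Series(row)
    for m in MODALITIES:
        vol = np.asarray(maps[m])
        if vol.shape != roi.mask.shape:
            raise ValueError(f"map {m!r} not on the ROI grid")
        stats = summary_stats(vol, roi, config)
        for s in _STAT_NAMES:
            row[f"{m}_{s}"] = stats[s]
        row[f"{m}_hotspot_mm3"] = hotspot_volume(vol, roi, config.threshold_for(m))
    row["empty_roi"] = False
    return pd.Series(row)
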