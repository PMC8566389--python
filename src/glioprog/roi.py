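"""Longitudinal ROI construction.

Two masks drive the whole feature extraction:

* the progressive-tumor ROI — voxels newly tumor-affected at the current
  exam: current non-necrotic tumor (contrast-enhancing or FLAIR-
  hyperintense) minus any voxel that carried *any* tumor label at the
  previous exam, minus current necrosis;
* the white-matter background mask — normal WM with all current tumor
  labels removed, used both as the DSC reference region and as the FET-PET
  background.

Pure set algebra on the shared grid; no morphological cleanup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthdata import NON_NECROTIC_TUMOR, TISSUE_WM, TUMOR_LABELS

__all__ = ["ProgressiveROI", "progressive_mask", "wm_background_mask"]


@dataclass
class ProgressiveROI:
    """Binary mask of newly tumor-affected, non-necrotic voxels."""

    mask: np.ndarray
    voxel_volume_mm3: float = 1.0
    provenance: str = ""

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3

    @property
    def is_empty(self) -> bool:
        return self.n_voxels == 0


def progressive_mask(seg_curr: np.ndarray, seg_prev: np.ndarray,
                     voxel_volume_mm3: float = 1.0,
                     provenance: str = "") -> ProgressiveROI:
    """Subtract the previous tumor segmentation from the current one and
    exclude necrosis. An empty result is valid (the case is flagged
    downstream, not dropped here)."""
    seg_curr = np.asarray(seg_curr)
    seg_prev = np.asarray(seg_prev)
    if seg_curr.shape != seg_prev.shape:
        raise ValueError(
            f"segmentation grids differ: {seg_curr.shape} vs {seg_prev.shape}")
    for seg, name in ((seg_curr, "current"), (seg_prev, "previous")):
        if not np.isin(seg, (0,) + TUMOR_LABELS).all():
            raise ValueError(f"{name} segmentation contains undefined label codes")
    mask = np.isin(seg_curr, NON_NECROTIC_TUMOR) & ~np.isin(seg_prev, TUMOR_LABELS)
    return ProgressiveROI(mask=mask, voxel_volume_mm3=float(voxel_volume_mm3),
                          provenance=provenance)


def wm_background_mask(tissue: np.ndarray, seg_curr: np.ndarray) -> np.ndarray:
    """Normal white matter with all current tumor labels excluded."""
    tissue = np.asarray(tissue)
    seg_curr = np.asarray(seg_curr)
    if tissue.shape != seg_curr.shape:
        raise ValueError(f"grids differ: {tissue.shape} vs {seg_curr.shape}")
    mask = (tissue == TISSUE_WM) & ~np.isin(seg_curr, TUMOR_LABELS)
    if not mask.any():
        raise ValueError("background undefined: no tumor-free white matter voxels")
    return mask
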