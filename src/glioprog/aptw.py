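"""APTw contrast: B0-corrected MTR asymmetry at +3.5 ppm.

The amide-proton-transfer-weighted (APTw) map is the magnetization-transfer-
ratio asymmetry of the Z-spectrum evaluated at +-3.5 ppm from water,

    APTw = 100 * [ Z(-3.5 ppm) - Z(+3.5 ppm) ],   Z(w) = S(w) / S_ref,

in percentage points. With only three samples per side (+-2.7, +-3.5,
+-4.3 ppm) each side is interpolated by the quadratic (Lagrange) polynomial
through its samples, and the evaluation point is shifted by the per-voxel
B0 field so that the asymmetry is taken symmetrically about the actual
water resonance.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .synthdata import ZSpectrumStack

__all__ = ["mtr_asymmetry", "MTRAsymmetry"]


def _lagrange_eval(nodes: np.ndarray, values: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Evaluate the interpolating polynomial through (nodes, values[..., j])
    at per-voxel points x. nodes: (m,), values: (..., m), x: (...)."""
    out = np.zeros(x.shape, dtype=float)
    m = nodes.size
    for j in range(m):
        w = np.ones_like(out)
        for k in range(m):
            if k != j:
                w *= (x - nodes[k]) / (nodes[j] - nodes[k])
        out += values[..., j] * w
    return out


def mtr_asymmetry(stack: ZSpectrumStack, eval_offset_ppm: float = 3.5,
                  b0_correct: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Compute the APTw volume (percentage points) from a Z-spectrum stack.

    Returns ``(aptw, valid)``; voxels whose B0 shift pushes the evaluation
    point outside the sampled offsets are flagged invalid (APTw set to 0).
    """
    offsets = np.asarray(stack.offsets_ppm, dtype=float)
    pos = np.sort(offsets[offsets > 0])
    neg = np.sort(offsets[offsets < 0])
    if pos.size < 3 or neg.size < 3:
        raise ValueError("need at least 3 sampled offsets per side")
    target = float(eval_offset_ppm)
    if not (pos.min() < target < pos.max()) or not (neg.min() < -target < neg.max()):
        raise ValueError(
            f"sampled offsets do not bracket the +-{target} ppm evaluation point")

    ref = np.asarray(stack.reference, dtype=float)
    if np.any(ref[np.isfinite(ref)] <= 0) and np.all(ref <= 0):
        raise ValueError("reference volume must be positive")
    ref_safe = np.where(ref > 0, ref, np.nan)
    z = np.asarray(stack.volumes, dtype=float) / ref_safe[..., None]

    b0 = np.asarray(stack.b0_shift_ppm, dtype=float) if b0_correct else 0.0
    x_pos = b0 + target        # evaluation point on the label side
    x_neg = b0 - target        # mirrored point on the reference side
    x_pos = np.broadcast_to(np.asarray(x_pos, float), z.shape[:-1])
    x_neg = np.broadcast_to(np.asarray(x_neg, float), z.shape[:-1])

    order = np.argsort(offsets)
    sorted_off = offsets[order]
    z_sorted = z[..., order]
    pos_idx = np.nonzero(sorted_off > 0)[0]
    neg_idx = np.nonzero(sorted_off < 0)[0]

    z_pos = _lagrange_eval(sorted_off[pos_idx], z_sorted[..., pos_idx], x_pos)
    z_neg = _lagrange_eval(sorted_off[neg_idx], z_sorted[..., neg_idx], x_neg)

    valid = ((x_pos >= pos.min()) & (x_pos <= pos.max())
             & (x_neg >= neg.min()) & (x_neg <= neg.max())
             & (ref > 0) & np.isfinite(z_pos) & np.isfinite(z_neg))
    aptw = 100.0 * (z_neg - z_pos)
    aptw = np.where(valid, aptw, 0.0)
    return aptw, valid


class MTRAsymmetry(TransformerMixin, BaseEstimator):
    """sklearn-style transformer form of :func:`mtr_asymmetry`.

    ``transform`` expects rows of ``[S(w_1) ... S(w_m), S_ref, b0_ppm]``
    (one voxel per row, offsets given at construction) and returns a single
    APTw column in percentage points.
    """

    def __init__(self, offsets_ppm=(-4.3, -3.5, -2.7, 2.7, 3.5, 4.3),
                 eval_offset_ppm: float = 3.5, b0_correct: bool = True):
        self.offsets_ppm = tuple(offsets_ppm)
        self.eval_offset_ppm = eval_offset_ppm
        self.b0_correct = b0_correct

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != len(self.offsets_ppm) + 2:
            raise ValueError("expected columns: offsets..., reference, b0")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        m = len(self.offsets_ppm)
        stack = ZSpectrumStack(
            volumes=X[:, None, None, :m],
            offsets_ppm=self.offsets_ppm,
            reference=X[:, None, None, m],
            b0_shift_ppm=X[:, None, None, m + 1],
        )
        aptw, _ = mtr_asymmetry(stack, self.eval_offset_ppm, self.b0_correct)
        return aptw.reshape(-1, 1)

    def get_feature_names_out(self, input_features=None):
        return np.array(["aptw_percent"])
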