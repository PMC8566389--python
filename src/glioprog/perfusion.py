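"""Leakage-corrected CBV from DSC perfusion time series.

The processing chain is the classical reference-curve approach:

1. convert signal to the relaxation-rate change
   DR2*(t) = -ln(S(t)/S0) / TE, with S0 the pre-bolus baseline mean;
2. average DR2*(t) over a tumor-excluded normal-white-matter mask to obtain
   the cohort reference curve R(t);
3. fit, per voxel, the two-regressor linear model
   DR2*(t) ~ K1 * R(t) - K2 * int_0^t R(tau) dtau
   so that blood-brain-barrier leakage (the running-integral term) is
   separated from the first-pass bolus; the leakage-corrected CBV is the
   K1-scaled integral of the reference curve;
4. normalize to relative CBV by anchoring the mean over normal white matter
   at 2.5%.

Signs follow the usual convention: T1-dominant extravasation (post-bolus
signal overshoot, DR2* undershoot) yields K2 > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .synthdata import _cumtrapz

WM_REFERENCE_PERCENT = 2.5

__all__ = [
    "DR2StarSeries", "CBVMaps", "signal_to_dr2star", "reference_curve",
    "leakage_corrected_cbv", "normalize_rcbv", "detect_bolus_arrival",
    "compute_cbv_maps", "CBVEstimator", "WM_REFERENCE_PERCENT",
]


@dataclass
class DR2StarSeries:
    """DR2*(t) in 1/s on the acquisition grid (last axis = dynamics)."""

    values: np.ndarray
    baseline_window: slice
    te_s: float
    tr_s: float
    valid: np.ndarray  # voxels with positive signal throughout the baseline


@dataclass
class CBVMaps:
    cbv_uncorrected: np.ndarray
    cbv_corrected: np.ndarray
    k2: np.ndarray
    rcbv_percent: np.ndarray | None = None
    wm_reference_value: float = WM_REFERENCE_PERCENT


def signal_to_dr2star(dsc: np.ndarray, te_s: float,
                      baseline_window: slice = slice(0, 15),
                      tr_s: float = 1.547) -> DR2StarSeries:
    """Convert a DSC signal series to DR2*(t) = -ln(S/S0)/TE.

    Voxels with non-positive baseline signal are flagged invalid (values
    set to 0) rather than propagating NaNs.
    """
    if te_s <= 0:
        raise ValueError("TE must be positive")
    n_base = len(range(*baseline_window.indices(dsc.shape[-1])))
    if n_base < 3:
        raise ValueError("baseline window must span at least 3 dynamics")
    s = np.asarray(dsc, dtype=np.float64)
    s0 = s[..., baseline_window].mean(axis=-1)
    valid = s0 > 0
    s0_safe = np.where(valid, s0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.clip(s / s0_safe[..., None], 1e-12, None)
        dr2 = -np.log(ratio) / te_s
    dr2[~valid] = 0.0
    return DR2StarSeries(values=dr2, baseline_window=baseline_window,
                         te_s=te_s, tr_s=tr_s, valid=valid)


def detect_bolus_arrival(dsc: np.ndarray, mask: np.ndarray) -> int:
    """Arrival dynamic = steepest drop of the mask-mean signal."""
    mean_sig = np.asarray(dsc, dtype=float)[mask].mean(axis=0)
    return int(np.argmin(np.diff(mean_sig)))


def reference_curve(dr2star: DR2StarSeries, reference_mask: np.ndarray) -> np.ndarray:
    """Voxel-mean DR2*(t) over a (tumor-excluded) reference mask."""
    mask = np.asarray(reference_mask, dtype=bool) & dr2star.valid
    if not mask.any():
        raise ValueError("reference mask is empty")
    return dr2star.values[mask].mean(axis=0)


def leakage_corrected_cbv(dr2star: DR2StarSeries, ref: np.ndarray,
                          bolus_start: int | None = None) -> CBVMaps:
    """Per-voxel two-regressor fit against the reference curve and its
    running integral; integrals use the trapezoidal rule over the window
    from bolus start to the last dynamic."""
    ref = np.asarray(ref, dtype=float)
    if ref.ndim != 1 or ref.size != dr2star.values.shape[-1]:
        raise ValueError("reference curve must cover the full dynamic range")
    if np.ptp(ref) <= 1e-12:
        raise ValueError("flat reference curve: leakage fit is rank-deficient")
    tr = dr2star.tr_s
    if bolus_start is None:
        bolus_start = dr2star.baseline_window.indices(ref.size)[1]

    ref_int = _cumtrapz(ref, dx=tr)
    design = np.stack([ref, -ref_int], axis=1)          # (T, 2)
    y = dr2star.values.reshape(-1, ref.size).T           # (T, n_vox)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)    # (2, n_vox)
    spatial = dr2star.values.shape[:-1]
    k1 = coef[0].reshape(spatial)
    k2 = coef[1].reshape(spatial)

    window = slice(bolus_start, ref.size)
    ref_area = np.trapezoid(ref[window], dx=tr)
    cbv_unc = np.trapezoid(dr2star.values[..., window], dx=tr, axis=-1)
    cbv_cor = k1 * ref_area
    cbv_unc[~dr2star.valid] = 0.0
    cbv_cor[~dr2star.valid] = 0.0
    k2[~dr2star.valid] = 0.0
    return CBVMaps(cbv_uncorrected=cbv_unc, cbv_corrected=cbv_cor, k2=k2)


def normalize_rcbv(cbv_corrected: np.ndarray, normal_wm_mask: np.ndarray) -> np.ndarray:
    """Anchor the normal-white-matter mean at 2.5%: the mean of the output
    over the mask equals 2.5 exactly."""
    mask = np.asarray(normal_wm_mask, dtype=bool)
    if not mask.any():
        raise ValueError("normal-WM mask is empty")
    wm_mean = float(np.asarray(cbv_corrected)[mask].mean())
    if wm_mean <= 0:
        raise ValueError(f"non-positive WM mean CBV ({wm_mean:.3g})")
    return np.asarray(cbv_corrected) / wm_mean * WM_REFERENCE_PERCENT


def compute_cbv_maps(dsc: np.ndarray, normal_wm_mask: np.ndarray,
                     te_s: float = 0.040, tr_s: float = 1.547,
                     baseline_window: slice = slice(0, 15)) -> CBVMaps:
    """Full chain: signal -> DR2* -> WM reference curve -> leakage-corrected
    CBV -> rCBV anchored at WM = 2.5%."""
    dr2 = signal_to_dr2star(dsc, te_s=te_s, baseline_window=baseline_window, tr_s=tr_s)
    ref = reference_curve(dr2, normal_wm_mask)
    maps = leakage_corrected_cbv(dr2, ref)
    maps.rcbv_percent = normalize_rcbv(maps.cbv_corrected, normal_wm_mask)
    return maps


class CBVEstimator(TransformerMixin, BaseEstimator):
    """sklearn-style wrapper around the reference-curve CBV chain.

    ``fit`` learns the reference curve from normal-white-matter voxel
    signals; ``transform`` maps per-voxel signal rows to
    ``[cbv_corrected, rcbv_percent, k2]`` columns.

    Parameters
    ----------
    te_s, tr_s : float
        Echo and repetition time in seconds.
    baseline : tuple of int
        Half-open dynamic range used as the pre-bolus S0 window.
    """

    def __init__(self, te_s: float = 0.040, tr_s: float = 1.547,
                 baseline: tuple[int, int] = (0, 15)):
        self.te_s = te_s
        self.tr_s = tr_s
        self.baseline = baseline

    def _dr2(self, X: np.ndarray) -> DR2StarSeries:
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("expected (n_voxels, n_dynamics)")
        return signal_to_dr2star(X, te_s=self.te_s, tr_s=self.tr_s,
                                 baseline_window=slice(*self.baseline))

    def fit(self, X: np.ndarray, y=None) -> "CBVEstimator":
        """X: (n_wm_voxels, n_dynamics) raw signals from normal WM."""
        dr2 = self._dr2(X)
        self.reference_curve_ = reference_curve(dr2, np.ones(X.shape[0], bool))
        wm_maps = leakage_corrected_cbv(dr2, self.reference_curve_)
        self.wm_mean_cbv_ = float(wm_maps.cbv_corrected.mean())
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "reference_curve_")
        maps = leakage_corrected_cbv(self._dr2(X), self.reference_curve_)
        rcbv = maps.cbv_corrected / self.wm_mean_cbv_ * WM_REFERENCE_PERCENT
        return np.column_stack([maps.cbv_corrected, rcbv, maps.k2])

    def get_feature_names_out(self, input_features=None):
        return np.array(["cbv_corrected", "rcbv_percent", "k2"])
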