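"""Leakage-corrected CBV: inverse-model exactness and round trips."""

import numpy as np
import pytest
from scipy.special import gamma as gamma_fn

from glioprog.perfusion import (
    CBVEstimator, compute_cbv_maps, leakage_corrected_cbv, normalize_rcbv,
    reference_curve, signal_to_dr2star,
)
from glioprog.roi import progressive_mask, wm_background_mask
from glioprog.synthdata import DSCAcquisition, generate_dsc_series

from conftest import noise_free_config
from glioprog.synthdata import generate_case

ACQ = DSCAcquisition()


def _dr2(signal, baseline=slice(0, 15)):
    return signal_to_dr2star(signal, te_s=ACQ.te_s, baseline_window=baseline,
                             tr_s=ACQ.tr_s)


def test_flat_signal_gives_zero_dr2star():
    sig = np.full((3, 80), 100.0)
    out = _dr2(sig)
    np.testing.assert_allclose(out.values, 0.0, atol=1e-12)
    assert out.valid.all()


def test_dr2star_inverts_exponential_forward_map(rng):
    x = rng.gamma(2.0, 3.0, size=(5, 80))
    x[:, :15] = 0.0
    sig = 100.0 * np.exp(-ACQ.te_s * x)
    np.testing.assert_allclose(_dr2(sig).values, x, rtol=1e-10, atol=1e-10)


def test_nonpositive_baseline_flags_voxel_invalid():
    sig = np.full((2, 80), 100.0)
    sig[1] = -1.0
    out = _dr2(sig)
    assert out.valid.tolist() == [True, False]
    np.testing.assert_array_equal(out.values[1], 0.0)


def test_trapezoid_integral_matches_gamma_variate_closed_form():
    # integral of the peak-normalized gamma variate: tp * e^a * Gamma(a+1) / a^(a+1)
    cbv = np.array([0.05])
    sig = generate_dsc_series(cbv, np.zeros(1), ACQ)
    dr2 = _dr2(sig)
    integral = np.trapezoid(dr2.values[0], dx=ACQ.tr_s)
    a = ACQ.bolus_shape_alpha
    closed = (cbv[0] * ACQ.cbv_to_dr2star * ACQ.bolus_time_to_peak_s
              * np.exp(a) * gamma_fn(a + 1) / a ** (a + 1))
    assert integral == pytest.approx(closed, rel=0.01)


def test_reference_curve_is_mask_mean():
    sig = generate_dsc_series(np.array([0.02, 0.02]), np.zeros(2), ACQ)
    dr2 = _dr2(sig)
    curve = reference_curve(dr2, np.array([True, True]))
    np.testing.assert_allclose(curve, dr2.values[0], rtol=1e-6)
    # two voxels with curves c and 3c average to 2c
    dr2.values = np.stack([dr2.values[0], 3 * dr2.values[0]])
    np.testing.assert_allclose(reference_curve(dr2, np.array([True, True])),
                               2 * dr2.values[0] / 1.0, rtol=1e-12)


def test_reference_curve_rejects_empty_mask():
    sig = generate_dsc_series(np.array([0.02]), np.zeros(1), ACQ)
    with pytest.raises(ValueError, match="empty"):
        reference_curve(_dr2(sig), np.array([False]))


def test_reference_curve_standard_error_scales_with_mask_size(rng):
    # pointwise SE of the mask-mean curve ~ sigma_voxel / sqrt(n)
    n_vox, n_draws, peak_dyn = 40, 100, 25
    curves, voxels = [], []
    for _ in range(n_draws):
        sig = generate_dsc_series(np.full(n_vox, 0.025), np.zeros(n_vox), ACQ,
                                  noise_sd=0.5, rng=rng)
        dr2 = _dr2(sig)
        curves.append(reference_curve(dr2, np.ones(n_vox, bool))[peak_dyn])
        voxels.append(dr2.values[0, peak_dyn])
    se_curve = np.std(curves)
    se_pred = np.std(voxels) / np.sqrt(n_vox)
    assert se_curve == pytest.approx(se_pred, rel=0.35)


def test_exact_model_fit_recovers_k1_two_k2_zero():
    sig = generate_dsc_series(np.array([0.025]), np.zeros(1), ACQ)
    dr2 = _dr2(sig)
    ref = dr2.values[0].copy()
    dr2.values = 2.0 * dr2.values
    maps = leakage_corrected_cbv(dr2, ref)
    assert maps.k2[0] == pytest.approx(0.0, abs=1e-8)
    expected = 2.0 * np.trapezoid(ref[15:], dx=ACQ.tr_s)
    assert maps.cbv_corrected[0] == pytest.approx(expected, rel=1e-6)


def test_flat_reference_curve_is_rejected():
    sig = generate_dsc_series(np.array([0.025]), np.zeros(1), ACQ)
    with pytest.raises(ValueError, match="rank-deficient|flat"):
        leakage_corrected_cbv(_dr2(sig), np.ones(80))


def test_leakage_correction_round_trip_noise_free():
    # WM voxels define the reference; tumor voxels leak
    cbv = np.concatenate([np.full(50, 0.025), np.full(10, 0.08)])
    leak = np.concatenate([np.zeros(50), np.full(10, -0.8)])  # T1-dominant
    sig = generate_dsc_series(cbv, leak, ACQ)
    dr2 = _dr2(sig)
    wm = np.arange(60) < 50
    ref = reference_curve(dr2, wm)
    maps = leakage_corrected_cbv(dr2, ref)
    rcbv = normalize_rcbv(maps.cbv_corrected, wm)
    np.testing.assert_allclose(rcbv[50:], 8.0, rtol=0.01)
    # T1-dominant leakage (signal overshoot) must surface as K2 > 0
    assert np.all(maps.k2[50:] > 0)
    assert np.all(maps.k2[:50] == pytest.approx(0.0, abs=1e-8))
    # the uncorrected integral is biased by the planted leakage term
    bias = np.abs(maps.cbv_uncorrected[50:] - maps.cbv_corrected[50:])
    assert np.all(bias > 0.1 * maps.cbv_corrected[50:])


def test_correction_is_noop_without_leakage():
    cbv = np.concatenate([np.full(30, 0.025), np.full(5, 0.06)])
    sig = generate_dsc_series(cbv, np.zeros(35), ACQ)
    dr2 = _dr2(sig)
    maps = leakage_corrected_cbv(dr2, reference_curve(dr2, np.arange(35) < 30))
    np.testing.assert_allclose(maps.cbv_corrected, maps.cbv_uncorrected,
                               rtol=1e-6, atol=1e-9)


def test_rcbv_is_invariant_to_global_signal_scaling():
    cbv = np.concatenate([np.full(30, 0.025), np.full(5, 0.08)])
    leak = np.concatenate([np.zeros(30), np.full(5, 0.5)])
    sig = generate_dsc_series(cbv, leak, ACQ)
    wm = np.arange(35) < 30
    r1 = compute_cbv_maps(sig, wm, te_s=ACQ.te_s, tr_s=ACQ.tr_s).rcbv_percent
    r2 = compute_cbv_maps(sig * 7.3, wm, te_s=ACQ.te_s, tr_s=ACQ.tr_s).rcbv_percent
    # signals are float32, so invariance holds to float32 precision
    np.testing.assert_allclose(r1, r2, rtol=1e-6)


def test_normalize_rcbv_contracts():
    vol = np.full((4, 4, 4), 3.7)
    wm = np.zeros((4, 4, 4), bool)
    wm[:2] = True
    np.testing.assert_allclose(normalize_rcbv(vol, wm), 2.5)
    vol2 = np.ones((8,))
    vol2[7] = 4.0
    mask = np.arange(8) < 7
    assert normalize_rcbv(vol2, mask)[7] == pytest.approx(10.0)
    with pytest.raises(ValueError):
        normalize_rcbv(vol, np.zeros((4, 4, 4), bool))
    with pytest.raises(ValueError):
        normalize_rcbv(-vol, wm)


def test_wm_mean_anchor_holds_exactly_on_synthetic_case(noisy_pd_case):
    case = noisy_pd_case
    wm_bg = wm_background_mask(case.tissue, case.seg_curr)
    maps = compute_cbv_maps(case.dsc, wm_bg, te_s=case.te_s, tr_s=case.tr_s,
                            baseline_window=slice(0, case.baseline_dynamics))
    assert maps.rcbv_percent[wm_bg].mean() == pytest.approx(2.5, abs=1e-12)


def test_planted_tumor_rcbv_recovered_through_full_chain():
    case = generate_case(noise_free_config(), "PD", 1)
    wm_bg = wm_background_mask(case.tissue, case.seg_curr)
    maps = compute_cbv_maps(case.dsc, wm_bg, te_s=case.te_s, tr_s=case.tr_s)
    roi = progressive_mask(case.seg_curr, case.seg_prev)
    median = np.median(maps.rcbv_percent[roi.mask])
    assert 7.9 <= median <= 8.1


def test_cbv_estimator_sklearn_surface():
    wm_sig = generate_dsc_series(np.full(40, 0.025), np.zeros(40), ACQ)
    tum_sig = generate_dsc_series(np.full(5, 0.08), np.full(5, 0.5), ACQ)
    est = CBVEstimator(te_s=ACQ.te_s, tr_s=ACQ.tr_s).fit(wm_sig)
    assert est.get_params()["te_s"] == ACQ.te_s
    out = est.transform(tum_sig)
    assert out.shape == (5, 3)
    np.testing.assert_allclose(out[:, 1], 8.0, rtol=0.01)  # rcbv column
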