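"""Synthetic multimodal cohort generator.

Emulates the per-case input bundle of a longitudinal neuro-oncology decision
point: BraTS-style tumor label maps at two timepoints, a GM/WM/CSF tissue
map, an FET-PET activity volume, a 4D DSC perfusion signal series, and a
sparse APTw Z-spectrum stack — all on one isotropic grid, with a binary
outcome label (PD = progressive disease, TRC = treatment-related changes).

Class effects are planted inside the newly tumor-affected region: PD cases
receive elevated tumor-to-background ratio (TBR), blood volume and APTw
levels; TRC cases attenuated ones. The planted ground-truth parameter maps
are retained on each case so the map-estimation modules can be checked by
forward–inverse round trips.

Geometry is deliberately simple — concentric ellipsoid shells
(necrosis ⊂ contrast-enhancing ⊂ FLAIR-hyperintense) whose previous-timepoint
radii are shrunken — the simplest shape that makes longitudinal subtraction,
necrosis exclusion and hot-spot fractions all non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np

# Segmentation label codes (BraTS-style convention used throughout)
BG, NECROSIS, FLAIR, ENHANCING = 0, 1, 2, 3
TUMOR_LABELS = (NECROSIS, FLAIR, ENHANCING)
NON_NECROTIC_TUMOR = (FLAIR, ENHANCING)

# Tissue label codes
TISSUE_BG, TISSUE_GM, TISSUE_WM, TISSUE_CSF = 0, 1, 2, 3

__all__ = [
    "EffectSizes", "DSCAcquisition", "ZSpecAcquisition", "TumorGeometry",
    "CohortConfig", "ZSpectrumStack", "GroundTruth", "StudyCase",
    "gamma_variate", "generate_dsc_series", "generate_zspectrum",
    "generate_case", "generate_cohort",
]


@dataclass
class EffectSizes:
    """Per-class mean levels planted inside non-necrotic tumor.

    tbr is a ratio (background = 1), rcbv_percent is on the scale where
    normal white matter averages 2.5, aptw_percent is MTR asymmetry in
    percentage points.
    """

    tbr: float
    rcbv_percent: float
    aptw_percent: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.tbr, self.rcbv_percent, self.aptw_percent)


@dataclass
class DSCAcquisition:
    """Echo-planar DSC timing; defaults follow a standard 3T protocol."""

    te_s: float = 0.040
    tr_s: float = 1.547
    n_dynamics: int = 80
    bolus_arrival_dyn: int = 20
    baseline_dynamics: int = 15  # pre-bolus dynamics used as S0 window
    bolus_time_to_peak_s: float = 8.0
    bolus_shape_alpha: float = 3.0
    s0: float = 100.0
    # converts a blood-volume fraction into a peak DR2* in 1/s (WM 2.5% -> 25/s)
    cbv_to_dr2star: float = 1000.0


@dataclass
class ZSpecAcquisition:
    """Sparse amide-CEST sampling: three offsets per side around +-3.5 ppm
    plus a far-off-resonance reference volume."""

    offsets_ppm: tuple[float, ...] = (-4.3, -3.5, -2.7, 2.7, 3.5, 4.3)
    reference_offset_ppm: float = -1560.0
    # broad direct-saturation/MT background, as under a 2 uT pulse train;
    # line widths chosen smooth enough for 3-point per-side interpolation
    water_amplitude: float = 0.9
    water_fwhm_ppm: float = 8.0
    amide_fwhm_ppm: float = 2.5
    reference_signal: float = 1000.0


@dataclass
class TumorGeometry:
    """Ellipsoid-shell tumor geometry, radii as fractions of the half-grid."""

    flair_radius_frac: tuple[float, float] = (0.42, 0.58)
    enhancing_frac_of_flair: float = 0.65
    necrosis_frac_of_enhancing: float = 0.5
    prev_scale_range: tuple[float, float] = (0.6, 0.8)
    center_jitter_frac: float = 0.06
    brain_radius_frac: float = 0.88
    csf_radius_frac: float = 0.18
    gm_rind_frac: float = 0.85  # GM occupies the brain shell outside this fraction


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    The default 57 PD / 17 TRC split mirrors a cohort whose majority-class
    (no-information) rate is 0.77. Effect means are chosen to straddle the
    literature hot-spot thresholds (TBR 2, rCBV 5.6, APTw 1.79) so that
    hot-spot volumetry separates the classes without being degenerate.
    """

    n_pd: int = 57
    n_trc: int = 17
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0
    pd_effects: EffectSizes = field(default_factory=lambda: EffectSizes(3.0, 8.0, 3.0))
    trc_effects: EffectSizes = field(default_factory=lambda: EffectSizes(1.5, 3.5, 1.0))
    # between-case SD of the planted tumor level, per modality
    effect_sd: EffectSizes = field(default_factory=lambda: EffectSizes(0.4, 1.5, 0.8))
    fet_noise_sd: float = 0.05      # activity units; background activity = 1
    dsc_noise_sd: float = 1.0       # signal units; S0 = 100
    zspec_noise_sd: float = 0.002   # in units of the normalized Z value
    b0_offset_sd_ppm: float = 0.05
    b0_gradient_sd_ppm: float = 0.10
    tumor_leakage_rate: float = 1.0  # 1/s per unit integrated bolus, in enhancing tumor
    dsc: DSCAcquisition = field(default_factory=DSCAcquisition)
    zspec: ZSpecAcquisition = field(default_factory=ZSpecAcquisition)
    geometry: TumorGeometry = field(default_factory=TumorGeometry)

    def __post_init__(self) -> None:
        if self.n_pd < 0 or self.n_trc < 0:
            raise ValueError("cohort sizes must be non-negative")
        if min(self.grid_shape) < 8:
            raise ValueError("grid too small for tumor geometry")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ZSpectrumStack:
    """Z-spectrum samples: one 3D volume per saturation offset, a
    far-off-resonance reference volume, and the per-voxel B0 shift field."""

    volumes: np.ndarray               # (..., n_offsets)
    offsets_ppm: tuple[float, ...]
    reference: np.ndarray             # (...,)
    b0_shift_ppm: np.ndarray          # (...,)
    reference_offset_ppm: float = -1560.0

    def __post_init__(self) -> None:
        if self.volumes.shape[-1] != len(self.offsets_ppm):
            raise ValueError("one volume per offset required")


@dataclass
class GroundTruth:
    """Planted per-voxel parameter maps retained for recovery tests."""

    tbr: np.ndarray
    cbv_fraction: np.ndarray
    aptw_percent: np.ndarray
    leakage_rate: np.ndarray
    params: dict


@dataclass
class StudyCase:
    """One decision point: two timepoints of tumor labels plus the
    current-timepoint multimodal volumes and the outcome label."""

    case_id: str
    label: str                      # "PD" or "TRC"
    seg_prev: np.ndarray
    seg_curr: np.ndarray
    tissue: np.ndarray
    fet: np.ndarray
    dsc: np.ndarray                 # (..., n_dynamics)
    zspec: ZSpectrumStack
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    te_s: float = 0.040
    tr_s: float = 1.547
    baseline_dynamics: int = 15
    truth: GroundTruth | None = None

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


# ----------------------------------------------------------------------------
# forward models


def gamma_variate(t_s: np.ndarray, arrival_s: float, time_to_peak_s: float,
                  alpha: float = 3.0) -> np.ndarray:
    """Peak-normalized gamma-variate bolus curve; zero before arrival."""
    t = np.asarray(t_s, dtype=float)
    x = (t - arrival_s) / time_to_peak_s
    c = np.where(x > 0, np.power(np.clip(x, 0, None), alpha)
                 * np.exp(alpha * (1.0 - x)), 0.0)
    return c


def _cumtrapz(y: np.ndarray, dx: float, axis: int = -1) -> np.ndarray:
    """Cumulative trapezoid with a leading zero, matching scipy's
    cumulative_trapezoid(initial=0)."""
    from scipy.integrate import cumulative_trapezoid

    return cumulative_trapezoid(y, dx=dx, axis=axis, initial=0.0)


def generate_dsc_series(true_cbv_fraction: np.ndarray,
                        leakage_rate: np.ndarray,
                        acq: DSCAcquisition | None = None,
                        noise_sd: float = 0.0,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Forward DSC signal model.

    S(t) = S0 * exp(-TE * DR2*(t)) with
    DR2*(t) = cbv_scale * C(t) + leakage_rate * int_0^t C(tau) dtau,
    where C is a gamma-variate bolus shared across voxels and cbv_scale is
    proportional to the blood-volume fraction. Pre-bolus dynamics carry
    DR2* = 0 up to noise.
    """
    acq = acq or DSCAcquisition()
    cbv = np.asarray(true_cbv_fraction, dtype=float)
    leak = np.asarray(leakage_rate, dtype=float)
    if not (np.all(np.isfinite(cbv)) and np.all(np.isfinite(leak))):
        raise ValueError("non-finite CBV fraction or leakage rate")
    if np.any(cbv < 0):
        raise ValueError("CBV fractions must be non-negative")
    if acq.bolus_arrival_dyn < 5:
        raise ValueError("need at least 5 pre-bolus baseline dynamics")

    t = np.arange(acq.n_dynamics) * acq.tr_s
    c = gamma_variate(t, acq.bolus_arrival_dyn * acq.tr_s,
                      acq.bolus_time_to_peak_s, acq.bolus_shape_alpha)
    c_int = _cumtrapz(c, dx=acq.tr_s)
    dr2 = (cbv[..., None] * acq.cbv_to_dr2star) * c + leak[..., None] * c_int
    signal = acq.s0 * np.exp(-acq.te_s * dr2)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return signal.astype(np.float32)


def _lorentzian(x_ppm: np.ndarray, fwhm_ppm: float) -> np.ndarray:
    hw = fwhm_ppm / 2.0
    return hw * hw / (hw * hw + np.square(x_ppm))


def generate_zspectrum(true_aptw_percent: np.ndarray,
                       b0_shift_ppm: np.ndarray,
                       acq: ZSpecAcquisition | None = None,
                       noise_sd: float = 0.0,
                       rng: np.random.Generator | None = None) -> ZSpectrumStack:
    """Forward Z-spectrum model.

    Z(w) = 1 - L(w; water) - A(w), with a water Lorentzian centered at
    0 ppm and an amide dip A centered at +3.5 ppm whose depth is scaled so
    that the noise-free MTR asymmetry evaluated at +-3.5 ppm equals
    ``true_aptw_percent`` exactly. The whole spectrum is shifted by the
    per-voxel B0 field before sampling at the nominal offsets.
    """
    acq = acq or ZSpecAcquisition()
    offsets = np.asarray(acq.offsets_ppm, dtype=float)
    if not ({3.5, 2.7, 4.3} <= set(np.round(np.abs(offsets), 6))):
        raise ValueError("offsets must cover +-3.5 ppm and +-(3.5 +- 0.8) ppm")
    aptw = np.asarray(true_aptw_percent, dtype=float)
    b0 = np.broadcast_to(np.asarray(b0_shift_ppm, dtype=float), aptw.shape)

    # amide amplitude: MTRasym(3.5) = amp * (A_norm(0) - A_norm(-7)) must
    # equal aptw/100; the small -7 ppm tail of the amide Lorentzian is
    # compensated analytically.
    tail = _lorentzian(np.array(-7.0), acq.amide_fwhm_ppm)
    amp = (aptw / 100.0) / (1.0 - tail)

    def z_model(w_eff: np.ndarray) -> np.ndarray:
        water = acq.water_amplitude * _lorentzian(w_eff, acq.water_fwhm_ppm)
        amide = amp * _lorentzian(w_eff - 3.5, acq.amide_fwhm_ppm)
        return 1.0 - water - amide

    vols = np.empty(aptw.shape + (offsets.size,), dtype=np.float32)
    for i, w in enumerate(offsets):
        vols[..., i] = acq.reference_signal * z_model(w - b0)
    reference = acq.reference_signal * z_model(acq.reference_offset_ppm - b0)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        scale = noise_sd * acq.reference_signal
        vols = vols + rng.normal(0.0, scale, size=vols.shape).astype(np.float32)
        reference = reference + rng.normal(0.0, scale, size=reference.shape)
    return ZSpectrumStack(
        volumes=vols,
        offsets_ppm=tuple(offsets),
        reference=reference.astype(np.float32),
        b0_shift_ppm=np.asarray(b0, dtype=np.float32).copy(),
        reference_offset_ppm=acq.reference_offset_ppm,
    )


# ----------------------------------------------------------------------------
# geometry and case assembly


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d <= 1.0


def _make_segmentation(shape, center, flair_radii, geom: TumorGeometry) -> np.ndarray:
    seg = np.zeros(shape, dtype=np.uint8)
    flair = _ellipsoid(shape, center, flair_radii)
    ce = _ellipsoid(shape, center, [r * geom.enhancing_frac_of_flair for r in flair_radii])
    nec = _ellipsoid(shape, center,
                     [r * geom.enhancing_frac_of_flair * geom.necrosis_frac_of_enhancing
                      for r in flair_radii])
    seg[flair] = FLAIR
    seg[ce] = ENHANCING
    seg[nec] = NECROSIS
    return seg


def generate_case(config: CohortConfig, label: str, case_seed: int) -> StudyCase:
    """Generate one synthetic decision point; deterministic in
    (config, label, case_seed)."""
    if label not in ("PD", "TRC"):
        raise ValueError(f"label must be 'PD' or 'TRC', got {label!r}")
    rng = np.random.default_rng([int(case_seed), int(config.seed)])
    shape = tuple(config.grid_shape)
    geom = config.geometry
    half = np.array(shape) / 2.0

    center = half + rng.uniform(-geom.center_jitter_frac, geom.center_jitter_frac,
                                size=3) * np.array(shape)
    flair_radii = rng.uniform(*geom.flair_radius_frac, size=3) * half
    if np.any(flair_radii >= half):
        raise ValueError("degenerate geometry: tumor radius exceeds half the grid")
    prev_scale = rng.uniform(*geom.prev_scale_range)

    seg_curr = _make_segmentation(shape, center, flair_radii, geom)
    seg_prev = _make_segmentation(shape, center, flair_radii * prev_scale, geom)

    brain = _ellipsoid(shape, half, half * geom.brain_radius_frac)
    csf = _ellipsoid(shape, half, half * geom.csf_radius_frac)
    gm_inner = _ellipsoid(shape, half, half * geom.brain_radius_frac * geom.gm_rind_frac)
    tissue = np.zeros(shape, dtype=np.uint8)
    tissue[brain] = TISSUE_GM
    tissue[gm_inner] = TISSUE_WM
    tissue[csf] = TISSUE_CSF

    # case-level planted levels: class mean + between-case dispersion
    effects = config.pd_effects if label == "PD" else config.trc_effects
    tbr_level = max(0.1, rng.normal(effects.tbr, config.effect_sd.tbr))
    rcbv_level = max(0.2, rng.normal(effects.rcbv_percent, config.effect_sd.rcbv_percent))
    aptw_level = rng.normal(effects.aptw_percent, config.effect_sd.aptw_percent)

    tumor = np.isin(seg_curr, NON_NECROTIC_TUMOR)
    necro = seg_curr == NECROSIS
    wm = tissue == TISSUE_WM
    gm = tissue == TISSUE_GM
    c_sf = tissue == TISSUE_CSF

    true_tbr = np.zeros(shape, dtype=float)
    true_tbr[brain] = 1.0
    true_tbr[gm] = 1.2
    true_tbr[c_sf] = 0.3
    true_tbr[wm] = 1.0
    true_tbr[tumor] = tbr_level
    true_tbr[necro] = 0.5

    true_cbv = np.zeros(shape, dtype=float)
    true_cbv[gm] = 0.05
    true_cbv[wm] = 0.025
    true_cbv[c_sf] = 0.01
    true_cbv[tumor] = rcbv_level / 100.0
    true_cbv[necro] = 0.005

    true_aptw = np.zeros(shape, dtype=float)
    true_aptw[tumor] = aptw_level

    leakage = np.zeros(shape, dtype=float)
    leakage[tumor] = config.tumor_leakage_rate

    # smooth B0 field: case-level offset plus a linear gradient along x
    b0_off = rng.normal(0.0, config.b0_offset_sd_ppm)
    b0_grad = rng.normal(0.0, config.b0_gradient_sd_ppm)
    x = (np.arange(shape[0]) / max(shape[0] - 1, 1)) - 0.5
    b0 = (b0_off + b0_grad * x)[:, None, None] * np.ones(shape)

    fet = true_tbr.copy()
    if config.fet_noise_sd > 0:
        fet = fet + rng.normal(0.0, config.fet_noise_sd, size=shape)
    fet = fet.astype(np.float32)

    # DSC is generated on brain voxels only; air carries the flat pre-bolus
    # signal (no contrast arrives there).
    dsc = np.full(shape + (config.dsc.n_dynamics,), config.dsc.s0, dtype=np.float32)
    dsc[brain] = generate_dsc_series(true_cbv[brain], leakage[brain], config.dsc,
                                     noise_sd=config.dsc_noise_sd, rng=rng)
    zspec = generate_zspectrum(true_aptw, b0, config.zspec,
                               noise_sd=config.zspec_noise_sd, rng=rng)

    truth = GroundTruth(
        tbr=true_tbr, cbv_fraction=true_cbv, aptw_percent=true_aptw,
        leakage_rate=leakage,
        params={"tbr": tbr_level, "rcbv_percent": rcbv_level,
                "aptw_percent": aptw_level, "label": label,
                "case_seed": int(case_seed)},
    )
    return StudyCase(
        case_id=f"case_{case_seed:04d}",
        label=label,
        seg_prev=seg_prev,
        seg_curr=seg_curr,
        tissue=tissue,
        fet=fet,
        dsc=dsc,
        zspec=zspec,
        spacing=tuple(config.voxel_spacing_mm),
        te_s=config.dsc.te_s,
        tr_s=config.dsc.tr_s,
        baseline_dynamics=config.dsc.baseline_dynamics,
        truth=truth,
    )


def generate_cohort(config: CohortConfig) -> Iterator[StudyCase]:
    """Yield the configured cohort case by case (PD cases first).

    Cases are generated lazily so a full cohort never needs to reside in
    memory at once.
    """
    if config.n_pd + config.n_trc < 1:
        raise ValueError("cohort must contain at least one case")
    idx = 0
    for _ in range(config.n_pd):
        yield generate_case(config, "PD", idx)
        idx += 1
    for _ in range(config.n_trc):
        yield generate_case(config, "TRC", idx)
        idx += 1
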