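"""Synthetic inputs for every stage of the pipeline, with ground truth.

The generators emulate the study's raw observables:

* single-voxel VSD sweeps — an alpha-shaped %ΔF/F EPSP transient converted
  through the spine's (quadratic) voltage sensitivity, riding on a
  photobleach × onset-transient baseline, with shot-like noise and a
  saturating 0.5 ms uncaging artifact, paired with interleaved control
  sweeps;
* optical/somatic bAP pairs with distance attenuation, the sensitivity
  nonlinearity and trial-to-trial temporal jitter;
* single-exponential FRAP recoveries;
* 3-D image stacks of a spine on a dendrite blurred by the anisotropic
  Gaussian PSF with Poisson photon noise.

Shot noise is approximated as Gaussian with SD ∝ √(baseline) (high photon
counts per sample); an exact Poisson flag is available on the image
generator where counts are low.  Cohort parameters default to the
population statistics of proximal basal spines of L5 pyramidal neurons:
EPSP amplitudes 13.0 ± 6.7 mV (truncated normal), half-widths 11.7 ± 4.3 ms,
τ_eq and R_neck log-normal (right-skewed, matched to mean 95 / median 72 ms
and mean 204 / median 161 MΩ respectively), optical bAP peaks
21.9 ± 4.9 %ΔF/F.  Identical seed + config give bit-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import vsd
from .calibrate import (
    DEFAULT_AP_MV,
    DEFAULT_LAMBDA_UM,
    SensitivityCurve,
    SpineCalibration,
)
from .frap import FrapConstants
from .traces import FrapTrace, OpticalTrace, SomaticTrace
from .volume import DEFAULT_VOXEL_ZYX, BinaryShape, PSFModel, blur_with_psf

__all__ = [
    "GroundTruth",
    "SynthConfig",
    "sample_cohort",
    "gen_vsd_epsp_trace",
    "gen_bap_trace",
    "gen_frap_trace",
    "gen_spine_stack",
    "SpineStackResult",
]


@dataclass
class GroundTruth:
    """True per-spine parameters behind one synthetic record."""

    record_id: int = 0
    amplitude_mv: float = 13.0
    half_width_ms: float = 11.7
    r_neck_mohm: float = 204.0
    volume_um3: float = 0.25
    tau_eq_ms: float = 95.0
    distance_um: float = 59.0
    sensitivity_pct_per_mv: float = 0.2   # small-signal, %ΔF/F per mV
    noise_sd_pct: float = 0.4             # post-filter-chain σ, %ΔF/F
    optical_bap_peak_dff: float = 21.9
    attenuation_ratio: float = 25.3       # spine/soma EPSP amplitude

    def __post_init__(self) -> None:
        positives = dict(
            half_width_ms=self.half_width_ms, r_neck_mohm=self.r_neck_mohm,
            volume_um3=self.volume_um3, tau_eq_ms=self.tau_eq_ms,
            sensitivity_pct_per_mv=self.sensitivity_pct_per_mv,
        )
        for name, val in positives.items():
            if val <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.amplitude_mv < 0 or self.noise_sd_pct < 0 or self.distance_um < 0:
            raise ValueError("amplitude, noise SD and distance must be ≥ 0")


@dataclass
class SynthConfig:
    """Generator configuration; identical seed + config ⇒ identical output."""

    seed: int = 0
    sampling_hz: float = 50_000.0
    duration_ms: float = 120.0
    uncaging_ms: float = 40.0
    artifact_ms: float = 0.5
    # baseline: F0·(1 + a_on·e^(−t/τ_on))·(1 − a_bl·(1 − e^(−t/τ_bl)))
    baseline_f0: float = 1000.0
    baseline_a_on: float = 0.04
    baseline_tau_on_ms: float = 15.0
    baseline_a_bl: float = 0.08
    baseline_tau_bl_ms: float = 400.0
    cohort_size: int = 48
    lambda_um: float = DEFAULT_LAMBDA_UM
    somatic_ap_mv: float = DEFAULT_AP_MV
    small_signal_fraction: float = 0.65
    shot_noise: bool = True  # SD ∝ √baseline; False = flat Gaussian

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_hz

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))

    def to_dict(self) -> dict:
        return asdict(self)


# population statistics emulated by the cohort sampler
COHORT_DEFAULTS = dict(
    amp_mean_mv=13.0, amp_sd_mv=6.7,
    fwhm_mean_ms=11.7, fwhm_sd_ms=4.3,
    rneck_median_mohm=161.0, rneck_mean_mohm=204.3,
    vol_median_um3=0.25, vol_sigma_log=0.5,
    bap_mean_dff=21.9, bap_sd_dff=4.9,
    dist_lo_um=30.0, dist_hi_um=110.0,
    noise_median_pct=0.4, noise_sigma_log=0.35,
)


def _salt(tag: str, *nums: int) -> int:
    """Deterministic per-record RNG salt (stable across processes)."""
    return zlib.crc32(("%s:%s" % (tag, nums)).encode())


def _lognormal_params(median: float, mean: float) -> tuple[float, float]:
    """(μ, σ) of a log-normal from its median and mean."""
    if mean <= median:
        raise ValueError("log-normal requires mean > median")
    mu = np.log(median)
    sigma = float(np.sqrt(2.0 * np.log(mean / median)))
    return float(mu), sigma


def sample_cohort(cfg: SynthConfig, n: int | None = None, **overrides) -> list[GroundTruth]:
    """Draw a cohort of spines from the configured population distributions.

    τ_eq is derived from the sampled (R_neck, Vol_head) through the
    diffusion relation, so the FRAP and attenuation estimation arms share a
    single ground truth.  Amplitudes use a normal truncated at zero; R_neck
    and volume are log-normal (right-skewed).
    """
    p = dict(COHORT_DEFAULTS, **overrides)
    n = n if n is not None else cfg.cohort_size
    rng = cfg.rng(salt=101)

    a, b = (0 - p["amp_mean_mv"]) / p["amp_sd_mv"], np.inf
    amps = stats.truncnorm.rvs(a, b, loc=p["amp_mean_mv"], scale=p["amp_sd_mv"],
                               size=n, random_state=rng)
    a2 = (1.0 - p["fwhm_mean_ms"]) / p["fwhm_sd_ms"]
    fwhms = stats.truncnorm.rvs(a2, np.inf, loc=p["fwhm_mean_ms"],
                                scale=p["fwhm_sd_ms"], size=n, random_state=rng)
    mu_r, sg_r = _lognormal_params(p["rneck_median_mohm"], p["rneck_mean_mohm"])
    rnecks = rng.lognormal(mu_r, sg_r, size=n)
    vols = rng.lognormal(np.log(p["vol_median_um3"]), p["vol_sigma_log"], size=n)
    consts = FrapConstants()
    # diffusion relation inverted: τ_eq[s] = R_neck[Ω]·Vol/(R_a[Ω·μm]·D)
    ra_ohm_um = consts.ra_ohm_cm * consts.OHM_CM_TO_OHM_UM
    taus = (rnecks * 1e6) * vols / (ra_ohm_um * consts.d_um2_s) * 1e3  # ms
    dists = rng.uniform(p["dist_lo_um"], p["dist_hi_um"], size=n)
    baps = np.clip(rng.normal(p["bap_mean_dff"], p["bap_sd_dff"], size=n), 5.0, None)
    noises = rng.lognormal(np.log(p["noise_median_pct"]), p["noise_sigma_log"], size=n)

    cohort = []
    for i in range(n):
        cal = SpineCalibration(
            distance_um=float(dists[i]),
            optical_bap_peak_dff=float(baps[i]),
            somatic_ap_mv=cfg.somatic_ap_mv,
            lambda_um=cfg.lambda_um,
            curve=SensitivityCurve(cfg.small_signal_fraction),
        )
        cohort.append(GroundTruth(
            record_id=i,
            amplitude_mv=float(amps[i]),
            half_width_ms=float(fwhms[i]),
            r_neck_mohm=float(rnecks[i]),
            volume_um3=float(vols[i]),
            tau_eq_ms=float(taus[i]),
            distance_um=float(dists[i]),
            sensitivity_pct_per_mv=cal.small_signal_sensitivity,
            noise_sd_pct=float(noises[i]),
            optical_bap_peak_dff=float(baps[i]),
        ))
    return cohort


def cohort_table(cohort: list[GroundTruth]) -> pd.DataFrame:
    return pd.DataFrame([asdict(g) for g in cohort])


# ---------------------------------------------------------------------------
# VSD EPSP sweeps
# ---------------------------------------------------------------------------

def _baseline(cfg: SynthConfig, t_ms: np.ndarray) -> np.ndarray:
    return (cfg.baseline_f0
            * (1.0 + cfg.baseline_a_on * np.exp(-t_ms / cfg.baseline_tau_on_ms))
            * (1.0 - cfg.baseline_a_bl * (1.0 - np.exp(-t_ms / cfg.baseline_tau_bl_ms))))


def _raw_noise_sd(cfg: SynthConfig, target_post_pct: float) -> float:
    """Per-sample raw noise SD (fraction of F0) whose post-filter-chain
    σ_noise — as measured by the moving 5 ms window estimator — equals the
    target in %ΔF/F."""
    gain = vsd.filter_noise_gain(cfg.dt_ms, window_ms=5.0)
    return (target_post_pct / 100.0) / gain


def _spine_curve_dff(truth: GroundTruth, cfg: SynthConfig, v_mv: np.ndarray) -> np.ndarray:
    """Convert a spine voltage waveform (mV) to %ΔF/F through the quadratic
    sensitivity of this spine."""
    curve = SensitivityCurve(cfg.small_signal_fraction)
    v_local_ap = cfg.somatic_ap_mv * np.exp(-truth.distance_um / cfg.lambda_um)
    u = np.asarray(v_mv, dtype=float) / v_local_ap
    return truth.optical_bap_peak_dff * curve(u)


def gen_vsd_epsp_trace(
    truth: GroundTruth, cfg: SynthConfig, trial: int = 0
) -> tuple[OpticalTrace, OpticalTrace]:
    """One uncaging sweep and its interleaved control sweep (raw counts).

    The uncaging sweep carries the alpha-shaped EPSP converted through the
    spine's nonlinear sensitivity, plus a saturating artifact during the
    0.5 ms uncaging pulse.  Both sweeps share the baseline model and the
    shot-like noise statistics.
    """
    if truth.amplitude_mv < 0:
        raise ValueError("amplitude must be non-negative")
    rng = cfg.rng(salt=_salt("epsp", truth.record_id, trial))
    t = np.arange(int(round(cfg.duration_ms / cfg.dt_ms))) * cfg.dt_ms
    base = _baseline(cfg, t)
    sd_frac = _raw_noise_sd(cfg, truth.noise_sd_pct)
    scale = np.sqrt(base / cfg.baseline_f0) if cfg.shot_noise else 1.0

    def noisy(signal_dff: np.ndarray) -> np.ndarray:
        mult = 1.0 + signal_dff / 100.0
        return base * mult + cfg.baseline_f0 * sd_frac * scale * rng.standard_normal(t.size)

    control = OpticalTrace(noisy(np.zeros_like(t)), dt=cfg.dt_ms, units="counts",
                           label="control", uncaging_time=cfg.uncaging_ms)

    if truth.amplitude_mv > 0:
        k1, k2 = vsd.rates_for_fwhm(truth.half_width_ms)
        shape = vsd.alpha_waveform(t - cfg.uncaging_ms, 1.0, k1, k2)
        ref = vsd.AlphaFit(K=1.0, k1=k1, k2=k2)
        v_wave = truth.amplitude_mv * shape / ref.amplitude
    else:
        v_wave = np.zeros_like(t)
    dff = _spine_curve_dff(truth, cfg, v_wave)
    samples = noisy(dff)
    artifact = (t >= cfg.uncaging_ms) & (t < cfg.uncaging_ms + cfg.artifact_ms)
    samples[artifact] = 10.0 * cfg.baseline_f0  # saturating uncaging artifact
    uncaging = OpticalTrace(samples, dt=cfg.dt_ms, units="counts", label="uncaging",
                            uncaging_time=cfg.uncaging_ms,
                            artifact_window=(cfg.uncaging_ms,
                                             cfg.uncaging_ms + cfg.artifact_ms))
    return uncaging, control


# ---------------------------------------------------------------------------
# bAP sweeps
# ---------------------------------------------------------------------------

def _ap_waveform(t_ms: np.ndarray, spike_ms: float, amp_mv: float,
                 tau_rise: float = 0.2, tau_fall: float = 1.2) -> np.ndarray:
    """Template biexponential action-potential waveform, peak = amp."""
    tt = np.clip(t_ms - (spike_ms - 1.0), 0.0, None)
    raw = np.exp(-tt / tau_fall) - np.exp(-tt / tau_rise)
    t_pk = np.log(tau_fall / tau_rise) / (1 / tau_rise - 1 / tau_fall)
    return amp_mv * raw / (np.exp(-t_pk / tau_fall) - np.exp(-t_pk / tau_rise))


def gen_bap_trace(
    truth: GroundTruth,
    cfg: SynthConfig,
    trial: int = 0,
    spike_ms: float = 20.0,
    jitter_sd_ms: float = 0.0,
    duration_ms: float = 50.0,
) -> tuple[OpticalTrace, SomaticTrace]:
    """A somatic AP sweep and its optical counterpart in the spine.

    The optical bAP is the somatic waveform attenuated by e^(−d/λ), passed
    through the quadratic sensitivity, plus noise; optional Gaussian
    temporal jitter shifts each trial's spike time.
    """
    rng = cfg.rng(salt=_salt("bap", truth.record_id, trial))
    t = np.arange(int(round(duration_ms / cfg.dt_ms))) * cfg.dt_ms
    jitter = rng.normal(0.0, jitter_sd_ms) if jitter_sd_ms > 0 else 0.0
    ts = spike_ms + jitter
    v_soma = _ap_waveform(t, ts, cfg.somatic_ap_mv)
    soma = SomaticTrace(v_soma, dt=cfg.dt_ms, spike_time=float(t[np.argmax(v_soma)]))

    # local bAP is the somatic waveform attenuated by e^(−d/λ); normalising
    # by the local peak, the attenuation cancels inside the curve argument
    curve = SensitivityCurve(cfg.small_signal_fraction)
    u = v_soma / cfg.somatic_ap_mv
    dff = truth.optical_bap_peak_dff * curve(np.clip(u, 0.0, None))
    sd_frac = _raw_noise_sd(cfg, truth.noise_sd_pct)
    samples = dff + 100.0 * sd_frac * rng.standard_normal(t.size)
    optical = OpticalTrace(samples, dt=cfg.dt_ms, units="pct_dff", label="bap")
    optical.meta["spike_time"] = soma.spike_time
    return optical, soma


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

def gen_frap_trace(
    truth: GroundTruth,
    cfg: SynthConfig,
    duration_ms: float = 800.0,
    dt_ms: float = 1.0,
    bleach_depth: float = 0.5,
    noise_sd: float = 0.0,
    pre_ms: float = 50.0,
) -> FrapTrace:
    """Single-exponential FRAP recovery with configurable bleach depth and
    fractional Gaussian noise; recovery window 600–1,000 ms typical."""
    if not 0 <= bleach_depth <= 1:
        raise ValueError("bleach depth must lie in [0, 1]")
    rng = cfg.rng(salt=_salt("frap", truth.record_id))
    t = np.arange(int(round((pre_ms + duration_ms) / dt_ms))) * dt_ms
    f = np.ones_like(t)
    post = t >= pre_ms
    tt = t[post] - pre_ms
    f_bleach = 1.0 - bleach_depth
    f[post] = 1.0 - (1.0 - f_bleach) * np.exp(-tt / truth.tau_eq_ms)
    if noise_sd > 0:
        f = f + noise_sd * rng.standard_normal(t.size)
    return FrapTrace(f, dt=dt_ms, bleach_time=pre_ms)


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

@dataclass
class SpineStackResult:
    stack: np.ndarray                     # noisy counts, [z, y, x]
    voxel_zyx: tuple[float, float, float]
    true_shape: BinaryShape               # head mask on a fine isotropic grid
    spine_roi: tuple[slice, slice]        # (y, x) on the max projection
    dendrite_roi: tuple[slice, slice]
    clean_stack: np.ndarray = field(repr=False, default=None)


def gen_spine_stack(
    truth: GroundTruth,
    psf: PSFModel | None = None,
    cfg: SynthConfig | None = None,
    voxel_zyx: tuple[float, float, float] = DEFAULT_VOXEL_ZYX,
    dendrite_diam_um: float = 2.0,
    neck_len_um: float = 0.7,
    neck_diam_um: float = 0.15,
    peak_counts: float = 100.0,
    fov_um: tuple[float, float, float] = (6.0, 4.5, 4.0),
    fine_um: float = 0.06,
    poisson: bool = True,
) -> SpineStackResult:
    """Render a dendrite + neck + spherical head scene, blur with the PSF and
    add Poisson photon noise.

    ``truth.volume_um3`` sets the head size (0 ⇒ dendrite only).  The binary
    head shape is returned on a fine isotropic grid ready for the
    erosion/dilation candidate series; sub-voxel geometry is handled by
    rendering occupancies on a z-supersampled grid.  ``peak_counts`` is the
    expected photon count in the thick dendrite (SNR ≈ √peak_counts).
    """
    psf = psf or PSFModel()
    cfg = cfg or SynthConfig()
    rng = cfg.rng(salt=_salt("stack", truth.record_id))
    vz, vy, vx = voxel_zyx
    z_sub = max(1, int(round(vz / vy)))

    nz = int(round(fov_um[2] / vz))
    ny = int(round(fov_um[1] / vy))
    nx = int(round(fov_um[0] / vx))
    zc = (np.arange(nz * z_sub) + 0.5) * (vz / z_sub)
    yc = (np.arange(ny) + 0.5) * vy
    xc = (np.arange(nx) + 0.5) * vx
    Z, Y, X = np.meshgrid(zc, yc, xc, indexing="ij")

    z0 = fov_um[2] / 2.0
    dend_y = 1.0
    r_dend = dendrite_diam_um / 2.0
    occ = ((Y - dend_y) ** 2 + (Z - z0) ** 2) <= r_dend**2

    r_head = (3.0 * truth.volume_um3 / (4.0 * np.pi)) ** (1.0 / 3.0) if truth.volume_um3 > 0 else 0.0
    head_y = dend_y + r_dend + neck_len_um + r_head
    head_x = fov_um[0] / 2.0
    if r_head > 0:
        occ |= ((X - head_x) ** 2 + (Y - head_y) ** 2 + (Z - z0) ** 2) <= r_head**2
        neck = (((X - head_x) ** 2 + (Z - z0) ** 2) <= (neck_diam_um / 2) ** 2) & \
               (Y >= dend_y + r_dend) & (Y <= head_y)
        occ |= neck

    # collapse the z-supersampling to native-frame occupancies
    occ = occ.reshape(nz, z_sub, ny, nx).mean(axis=1)
    clean = blur_with_psf(occ, psf, voxel_zyx) * peak_counts
    if poisson:
        stack = rng.poisson(np.clip(clean, 0, None)).astype(float)
    else:
        stack = clean + np.sqrt(np.clip(clean, 0, None)) * rng.standard_normal(clean.shape)

    # true head shape on the fine isotropic grid
    if r_head > 0:
        half = r_head + 4 * fine_um
        ax = np.arange(-half, half + fine_um, fine_um)
        Zf, Yf, Xf = np.meshgrid(ax, ax, ax, indexing="ij")
        head_mask = (Xf**2 + Yf**2 + Zf**2) <= r_head**2
    else:
        head_mask = np.zeros((1, 1, 1), dtype=bool)
    true_shape = BinaryShape(head_mask, voxel_zyx=(fine_um,) * 3)

    # ROIs on the (y, x) max projection
    pad_um = 0.35
    y_lo = int(max(0, (head_y - r_head - pad_um) / vy))
    y_hi = int(min(ny, (head_y + r_head + pad_um) / vy + 1))
    x_lo = int(max(0, (head_x - r_head - pad_um) / vx))
    x_hi = int(min(nx, (head_x + r_head + pad_um) / vx + 1))
    spine_roi = (slice(y_lo, y_hi), slice(x_lo, x_hi))
    d_lo = int(max(0, (dend_y - r_dend) / vy))
    d_hi = int((dend_y + r_dend) / vy + 1)
    dendrite_roi = (slice(d_lo, d_hi), slice(0, nx))

    return SpineStackResult(stack=stack, voxel_zyx=voxel_zyx, true_shape=true_shape,
                            spine_roi=spine_roi, dendrite_roi=dendrite_roi,
                            clean_stack=clean)
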