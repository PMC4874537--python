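"""End-to-end synthetic experiments and cohort statistics.

``run_epsp_experiment`` chains trace generation → filtering/detection →
calibration → attenuation-based R_neck inference; ``run_frap_experiment``
chains stack + FRAP generation → volume estimation → the diffusion
relation.  ``summarize`` reproduces the descriptive-statistics table
(mean, SD, SE, median, range, percentile-bootstrap 95% CI).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import synth, vsd
from .cable import (
    AttenuationCurve,
    CableModel,
    PassiveParams,
    SpineSynapse,
    discretize,
    infer_rneck,
    scan_locations,
    synthetic_l5_tree,
)
from .calibrate import SpineCalibration, SensitivityCurve, dff_to_mv, voltage_detection_limit
from .frap import fit_recovery, r_neck_from_frap
from .synth import GroundTruth, SynthConfig
from .volume import PSFModel, candidate_series, dilution_ratio, match_size

__all__ = [
    "CohortSummary",
    "summarize",
    "ks_two_sample",
    "run_epsp_experiment",
    "run_frap_experiment",
    "default_attenuation_curves",
    "infer_rneck_from_cohort",
]

DEFAULT_BOOTSTRAP_RESAMPLES = 400_000


@dataclass
class CohortSummary:
    """Descriptive statistics with a percentile-bootstrap CI for the mean."""

    n: int
    mean: float
    sd: float
    se: float
    median: float
    minimum: float
    maximum: float
    ci_low: float
    ci_high: float
    n_boot: int

    def as_row(self) -> dict:
        return asdict(self)


def summarize(
    values,
    n_boot: int = DEFAULT_BOOTSTRAP_RESAMPLES,
    seed: int = 0,
    ci: float = 0.95,
) -> CohortSummary:
    """Mean/SD/SE/median/min/max plus a seeded percentile-bootstrap CI of
    the mean (default 400,000 resamples)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarise an empty sample")
    rng = np.random.default_rng(seed)
    if x.size == 1 or np.ptp(x) == 0:
        lo = hi = float(np.mean(x))
    else:
        # resample in blocks so n_boot × n never exhausts memory
        block = max(1, int(2e7 // x.size))
        means = np.empty(n_boot)
        done = 0
        while done < n_boot:
            m = min(block, n_boot - done)
            idx = rng.integers(0, x.size, size=(m, x.size))
            means[done : done + m] = x[idx].mean(axis=1)
            done += m
        alpha = (1.0 - ci) / 2.0
        lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return CohortSummary(
        n=int(x.size),
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        se=float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0,
        median=float(np.median(x)),
        minimum=float(np.min(x)),
        maximum=float(np.max(x)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
    )


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov statistic and p-value."""
    res = stats.ks_2samp(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)


def _config_hash(cfg: SynthConfig) -> str:
    return hashlib.sha256(json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def _add_provenance(table: pd.DataFrame, cfg: SynthConfig) -> None:
    from . import __version__

    table["seed"] = cfg.seed
    table["config_hash"] = _config_hash(cfg)
    table["spinevolt_version"] = __version__


def default_attenuation_curves(
    r_neck_grid=(1.0, 100.0, 200.0, 350.0, 500.0),
    n_sites: int = 31,
    model: CableModel | None = None,
    spine: SpineSynapse | None = None,
    dt_ms: float = 0.025,
) -> tuple[list[AttenuationCurve], CableModel]:
    """Attenuation-vs-distance curves on the default synthetic tree.

    The site count is reduced from the full basal sweep for routine use;
    the curves are smooth in distance so the quadratic fits are insensitive
    to this choice.
    """
    if model is None:
        # finer spatial grid than the solver default: site placement and
        # distance resolution matter more than raw speed here
        model = discretize(synthetic_l5_tree(), PassiveParams(),
                           max_fraction_of_lambda=0.02)
    spine = spine or SpineSynapse()
    curves, _ = scan_locations(model, spine, r_neck_grid, n_sites=n_sites, dt_ms=dt_ms)
    return curves, model


def infer_rneck_from_cohort(
    cfg: SynthConfig,
    curves: list[AttenuationCurve],
    n_spines: int | None = None,
    ratio_noise_sd: float = 0.08,
    cohort: list[GroundTruth] | None = None,
):
    """Model-arm R_neck estimates for a sampled cohort, without the optical
    chain: each spine's attenuation ratio is read off the curves at its
    distance (plus measurement noise) and inverted back to R_neck."""
    if cohort is None:
        cohort = synth.sample_cohort(cfg, n=n_spines)
    rng = cfg.rng(salt=777)
    ordered = sorted(curves, key=lambda c: c.r_neck_mohm)
    grid = [c.r_neck_mohm for c in ordered]
    pts = []
    for truth in cohort:
        ratio = float(np.interp(truth.r_neck_mohm, grid,
                                [c(truth.distance_um) for c in ordered]))
        if ratio_noise_sd > 0:
            ratio *= 1.0 + ratio_noise_sd * rng.standard_normal()
        pts.append((truth.distance_um, ratio))
    return infer_rneck(curves, pts), cohort


def _process_one_spine(
    truth: GroundTruth, cfg: SynthConfig, n_sweeps: int
) -> dict:
    """Average sweeps, filter, subtract baseline, estimate noise, detect and
    calibrate one spine's uncaging experiment."""
    unc_sum = None
    ctl_sum = None
    for trial in range(n_sweeps):
        unc, ctl = synth.gen_vsd_epsp_trace(truth, cfg, trial=trial)
        unc = vsd.remove_uncaging_artifact(unc)
        unc_sum = unc.samples if unc_sum is None else unc_sum + unc.samples
        ctl_sum = ctl.samples if ctl_sum is None else ctl_sum + ctl.samples
    unc_avg = unc.with_samples(unc_sum / n_sweeps)
    ctl_avg = ctl.with_samples(ctl_sum / n_sweeps)

    unc_f = vsd.lowpass_epsp(unc_avg)
    ctl_f = vsd.lowpass_epsp(ctl_avg)
    # baseline fitted on the averaged uncaging sweep itself (response window
    # excluded) so its slow fluctuations are absorbed; the control average
    # gets its own fit for the noise estimate
    response = (cfg.uncaging_ms, min(cfg.uncaging_ms + 60.0, cfg.duration_ms))
    bleach_unc = vsd.fit_bleach(unc_f, exclude_window=response)
    bleach_ctl = vsd.fit_bleach(ctl_f)
    unc_dff = vsd.subtract_bleach(unc_f, bleach_unc)
    ctl_dff = vsd.subtract_bleach(ctl_f, bleach_ctl)
    noise = vsd.estimate_noise(ctl_dff)

    kernel = vsd.chain_impulse_response(cfg.dt_ms)
    det = vsd.detect_and_fit(unc_dff, noise, uncaging_time=cfg.uncaging_ms,
                             filter_kernel=kernel)
    cal = SpineCalibration(
        distance_um=truth.distance_um,
        optical_bap_peak_dff=truth.optical_bap_peak_dff,
        somatic_ap_mv=cfg.somatic_ap_mv,
        lambda_um=cfg.lambda_um,
        curve=SensitivityCurve(cfg.small_signal_fraction),
    )
    row = dict(
        record_id=truth.record_id,
        true_amplitude_mv=truth.amplitude_mv,
        true_half_width_ms=truth.half_width_ms,
        distance_um=truth.distance_um,
        sigma_noise_pct=noise.sigma,
        detected=det.detected,
        limit_mv=voltage_detection_limit(noise, cal),
    )
    if det.detected:
        row["amplitude_dff"] = det.fit.amplitude
        row["amplitude_mv"] = dff_to_mv(det.fit.amplitude, cal)
        row["half_width_ms"] = det.fit.fwhm
    else:
        row["amplitude_dff"] = np.nan
        row["amplitude_mv"] = np.nan
        row["half_width_ms"] = np.nan
    return row


def run_epsp_experiment(
    cfg: SynthConfig,
    n_spines: int | None = None,
    n_sweeps: int = 10,
    curves: list[AttenuationCurve] | None = None,
    n_boot: int = 10_000,
    ratio_noise_sd: float = 0.0,
) -> dict:
    """Synthetic analogue of the uncaging campaign.

    Generates a cohort, runs the full optical chain per spine, summarises
    amplitudes/half-widths, and — when attenuation curves are supplied —
    infers R_neck from each spine's (distance, attenuation ratio), the
    ratio taken from the spine's ground truth with optional measurement
    noise.  Every output row carries the seed and config hash.
    """
    cohort = synth.sample_cohort(cfg, n=n_spines)
    rows = [_process_one_spine(truth, cfg, n_sweeps) for truth in cohort]
    table = pd.DataFrame(rows)
    _add_provenance(table, cfg)

    detected = table[table["detected"]]
    out = {"per_spine": table}
    if len(detected):
        out["amplitude_summary"] = summarize(detected["amplitude_mv"], n_boot=n_boot,
                                             seed=cfg.seed)
        out["half_width_summary"] = summarize(detected["half_width_ms"], n_boot=n_boot,
                                              seed=cfg.seed)
    if curves is not None:
        inference, _ = infer_rneck_from_cohort(cfg, curves, cohort=cohort,
                                               ratio_noise_sd=ratio_noise_sd)
        out["rneck_inference"] = inference
        if inference.estimates.size:
            out["rneck_summary"] = summarize(inference.estimates, n_boot=n_boot,
                                             seed=cfg.seed)
    return out


def run_frap_experiment(
    cfg: SynthConfig,
    n_spines: int | None = None,
    frap_noise_sd: float = 0.05,
    estimate_volume: bool = False,
    psf: PSFModel | None = None,
    n_boot: int = 10_000,
) -> dict:
    """Synthetic analogue of the FRAP campaign: recovery fits plus head
    volumes (ground-truth volumes by default; PSF-matched estimates from
    rendered stacks when ``estimate_volume`` is set) → R_neck via the
    diffusion relation."""
    cohort = synth.sample_cohort(cfg, n=n_spines)
    psf = psf or PSFModel()
    rows = []
    for truth in cohort:
        trace = synth.gen_frap_trace(truth, cfg, noise_sd=frap_noise_sd)
        fit = fit_recovery(trace)
        if fit.undefined:
            rows.append(dict(record_id=truth.record_id, tau_eq_ms=np.nan,
                             vol_um3=np.nan, r_neck_mohm=np.nan, flag="undefined_fit"))
            continue
        if estimate_volume:
            scene = synth.gen_spine_stack(truth, psf, cfg)
            ratio = dilution_ratio(scene.stack, scene.spine_roi, scene.dendrite_roi)
            cands, idx = candidate_series(scene.true_shape, n_steps=4, iso_um=None)
            est = match_size(cands, psf, ratio, dilation_indices=idx)
            vol = est.volume_um3
        else:
            vol = truth.volume_um3
        est = r_neck_from_frap(fit, vol)
        rows.append(dict(record_id=truth.record_id, tau_eq_ms=fit.tau_eq_ms,
                         vol_um3=vol, r_neck_mohm=est.r_neck_mohm, flag=""))
    table = pd.DataFrame(rows)
    _add_provenance(table, cfg)
    ok = table[table["flag"] == ""]
    out = {"per_spine": table}
    if len(ok):
        out["tau_summary"] = summarize(ok["tau_eq_ms"], n_boot=n_boot, seed=cfg.seed)
        out["rneck_summary"] = summarize(ok["r_neck_mohm"], n_boot=n_boot, seed=cfg.seed)
    return out
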