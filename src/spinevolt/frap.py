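"""Spine-neck resistance from dye diffusion (FRAP).

After bleaching a cytosolic dye in the spine head, fluorescence recovers by
diffusion through the neck with a single-exponential time course
F(t) = F∞ − (F∞ − F_bleach)·e^(−t/τ_eq).  Because the same neck geometry
limits both dye diffusion and electrical current, the neck resistance
follows from the equilibration time constant and the head volume:

    R_neck = R_a · τ_eq · D / Vol_head

with cytoplasmic resistivity R_a (default 150 Ω·cm), dye diffusion
coefficient D (AlexaFluor 488, default 380 μm²/s) and head volume in μm³.
All unit bookkeeping is centralised in :class:`FrapConstants`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .traces import FrapTrace

__all__ = ["FrapConstants", "FrapFit", "NeckEstimate", "fit_recovery", "r_neck_from_frap"]


@dataclass(frozen=True)
class FrapConstants:
    """Physical constants of the diffusion→resistance conversion."""

    ra_ohm_cm: float = 150.0      # cytoplasmic resistivity
    d_um2_s: float = 380.0        # dye diffusion coefficient

    OHM_CM_TO_OHM_UM = 1.0e4      # 1 Ω·cm = 10⁴ Ω·μm
    MS_TO_S = 1.0e-3
    OHM_TO_MOHM = 1.0e-6

    def r_neck_mohm(self, tau_eq_ms: float, vol_um3: float) -> float:
        """R_a·τ_eq·D/Vol in MΩ (τ in ms, Vol in μm³)."""
        ra_ohm_um = self.ra_ohm_cm * self.OHM_CM_TO_OHM_UM
        r_ohm = ra_ohm_um * (tau_eq_ms * self.MS_TO_S) * self.d_um2_s / vol_um3
        return r_ohm * self.OHM_TO_MOHM


@dataclass
class FrapFit:
    """Single-exponential recovery fit."""

    tau_eq_ms: float
    amplitude: float          # F∞ − F_bleach (recovery depth)
    asymptote: float          # F∞
    residual_norm: float = 0.0
    undefined: bool = False   # set when bleach depth is below noise

    def __post_init__(self) -> None:
        if not self.undefined and self.tau_eq_ms <= 0:
            raise ValueError("τ_eq must be positive")


@dataclass
class NeckEstimate:
    """R_neck inferred from one spine's (τ_eq, Vol_head)."""

    r_neck_mohm: float
    tau_eq_ms: float
    vol_um3: float
    constants: FrapConstants


def fit_recovery(trace: FrapTrace, min_depth_sigma: float = 2.0) -> FrapFit:
    """Fit F(t) = F∞ − (F∞ − F_b)·e^(−t/τ) to the post-bleach samples.

    Initialisation is log-linear: with F∞ taken from the tail,
    ln(F∞ − F(t)) is linear in t with slope −1/τ; the estimate is then
    refined by nonlinear least squares.  Returns an undefined fit when the
    bleach depth does not exceed ``min_depth_sigma`` times the pre-bleach
    noise SD (nothing to recover from).
    """
    t = trace.times
    post = t >= trace.bleach_time
    if post.sum() < 4:
        raise ValueError("too few post-bleach samples")
    tt = t[post] - trace.bleach_time
    y = trace.samples[post]

    pre = trace.samples[~post]
    baseline = float(np.mean(pre)) if pre.size else float(np.max(y))
    noise_sd = float(np.std(pre)) if pre.size > 3 else 0.0
    depth = baseline - float(y[0])
    if depth <= max(min_depth_sigma * noise_sd, 1e-12 * max(abs(baseline), 1.0)):
        return FrapFit(tau_eq_ms=float("nan"), amplitude=0.0, asymptote=baseline,
                       undefined=True)

    # log-linear initialisation
    f_inf0 = float(np.mean(y[-max(3, y.size // 10):]))
    gap = f_inf0 - y
    ok = gap > 1e-6 * depth
    if ok.sum() >= 3:
        slope, intercept = np.polyfit(tt[ok], np.log(gap[ok]), 1)
        tau0 = -1.0 / slope if slope < 0 else float(tt[-1]) / 3.0
    else:
        tau0 = float(tt[-1]) / 3.0
    tau0 = float(np.clip(tau0, float(tt[1]), 10 * float(tt[-1])))
    a0 = f_inf0 - float(y[0])

    def model(p):
        f_inf, a, log_tau = p
        return f_inf - a * np.exp(-tt / np.exp(log_tau))

    res = optimize.least_squares(lambda p: model(p) - y,
                                 [f_inf0, a0, np.log(tau0)], max_nfev=2000)
    f_inf, a, log_tau = res.x
    tau = float(np.exp(log_tau))
    # a recovery much slower than the monitoring window (or a negative
    # recovery) is not measurable from this trace
    if a <= 0 or tau > 5.0 * float(tt[-1]):
        return FrapFit(tau_eq_ms=float("nan"), amplitude=float(a),
                       asymptote=float(f_inf), undefined=True)
    fit = FrapFit(tau_eq_ms=tau, amplitude=float(a), asymptote=float(f_inf))
    fit.residual_norm = float(np.linalg.norm(res.fun))
    return fit


def r_neck_from_frap(
    fit: FrapFit, vol_um3: float, constants: FrapConstants | None = None
) -> NeckEstimate:
    """Convert a recovery fit and a head volume into a neck resistance."""
    if vol_um3 <= 0:
        raise ValueError("head volume must be positive")
    if fit.undefined or not np.isfinite(fit.tau_eq_ms):
        raise ValueError("cannot convert an undefined recovery fit")
    c = constants or FrapConstants()
    return NeckEstimate(
        r_neck_mohm=c.r_neck_mohm(fit.tau_eq_ms, vol_um3),
        tau_eq_ms=fit.tau_eq_ms,
        vol_um3=vol_um3,
        constants=c,
    )
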