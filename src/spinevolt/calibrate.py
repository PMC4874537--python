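"""Per-spine conversion of optical %ΔF/F to membrane potential in mV.

Calibration uses the backpropagating action potential (bAP) recorded
optically in the same spine and electrically at the soma.  Three steps:

1. the dye's voltage sensitivity is slightly sublinear; a two-parameter
   quadratic normalised response y(v) = α·v + β·v², pinned to y(0)=0 and
   y(V_AP)=1, captures it.  The small-signal fraction s = α·V_AP (default
   0.65) is the ratio of the sensitivity near rest to the secant sensitivity
   at the AP peak;
2. the dye sensitivity in the particular spine is the optical bAP peak over
   the *local* bAP amplitude;
3. the local bAP amplitude is the somatic AP amplitude attenuated by
   e^(−d/λ) with length constant λ = 400 μm along basal dendrites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .vsd import NoiseEstimate, THRESHOLD_MULT

__all__ = [
    "SensitivityCurve",
    "SpineCalibration",
    "fit_nonlinearity",
    "bap_attenuation",
    "calibrate_spine",
    "dff_to_mv",
    "voltage_detection_limit",
    "DEFAULT_LAMBDA_UM",
    "DEFAULT_SMALL_SIGNAL_FRACTION",
    "DEFAULT_AP_MV",
]

DEFAULT_LAMBDA_UM = 400.0
DEFAULT_SMALL_SIGNAL_FRACTION = 0.65
DEFAULT_AP_MV = 100.0  # somatic AP amplitude assumed when not recorded


@dataclass
class SensitivityCurve:
    """Normalised optical response y(u) = s·u + (1−s)·u² on u = v/V_AP.

    ``s`` ∈ (0, 1] is the small-signal fraction; s = 1 is a perfectly linear
    dye.  y is monotone increasing on [0, 1] for s > 0 and satisfies
    y(0) = 0, y(1) = 1 by construction.
    """

    small_signal_fraction: float = DEFAULT_SMALL_SIGNAL_FRACTION

    def __post_init__(self) -> None:
        if not 0 < self.small_signal_fraction <= 1 + 1e-12:
            raise ValueError("small-signal fraction must lie in (0, 1]")

    @property
    def s(self) -> float:
        return self.small_signal_fraction

    def __call__(self, u):
        u = np.asarray(u, dtype=float)
        return self.s * u + (1.0 - self.s) * u**2

    def invert(self, y):
        """Positive root of s·u + (1−s)·u² = y."""
        y = np.asarray(y, dtype=float)
        if np.any(y < 0):
            raise ValueError("normalised response must be non-negative")
        b = 1.0 - self.s
        # cancellation-free form of the positive quadratic root
        return 2.0 * y / (self.s + np.sqrt(self.s**2 + 4.0 * b * y))


def fit_nonlinearity(v_mv: np.ndarray, y_norm: np.ndarray, v_ap: float) -> SensitivityCurve:
    """Fit the quadratic sensitivity curve to binned (voltage, normalised
    optical) pairs from juxtasomatic paired recordings.

    With both endpoint constraints imposed the family has the single free
    parameter s, fitted by linear least squares on y − u² = s·(u − u²).
    """
    u = np.asarray(v_mv, dtype=float) / v_ap
    y = np.asarray(y_norm, dtype=float)
    x = u - u**2
    denom = float(np.dot(x, x))
    if denom == 0:
        raise ValueError("degenerate calibration data (all points at endpoints)")
    s = float(np.dot(x, y - u**2) / denom)
    s = min(s, 1.0)
    if s <= 0:
        raise ValueError("fitted sensitivity curve is non-monotone on [0, V_AP]")
    return SensitivityCurve(small_signal_fraction=s)


def bap_attenuation(d_um: float, lambda_um: float = DEFAULT_LAMBDA_UM) -> float:
    """Amplitude attenuation e^(−d/λ) of the bAP at distance d from the soma."""
    if d_um < 0 or lambda_um <= 0:
        raise ValueError("distance must be ≥ 0 and λ > 0")
    return float(np.exp(-d_um / lambda_um))


@dataclass
class SpineCalibration:
    """Everything needed to convert %ΔF/F in one spine to mV.

    ``peak_sensitivity`` is the secant sensitivity at the local bAP peak,
    optical-peak / (somatic AP × e^(−d/λ)), in %ΔF/F per mV;
    ``small_signal_sensitivity`` = s × peak sensitivity applies near rest.
    """

    distance_um: float
    optical_bap_peak_dff: float
    somatic_ap_mv: float = DEFAULT_AP_MV
    lambda_um: float = DEFAULT_LAMBDA_UM
    curve: SensitivityCurve = field(default_factory=SensitivityCurve)

    def __post_init__(self) -> None:
        if self.optical_bap_peak_dff <= 0 or self.somatic_ap_mv <= 0:
            raise ValueError("bAP amplitudes must be positive")
        if self.distance_um < 0:
            raise ValueError("distance must be non-negative")

    @property
    def attenuation(self) -> float:
        return bap_attenuation(self.distance_um, self.lambda_um)

    @property
    def local_bap_mv(self) -> float:
        """bAP amplitude at the spine, mV."""
        return self.somatic_ap_mv * self.attenuation

    @property
    def peak_sensitivity(self) -> float:
        """%ΔF/F per mV at the local bAP peak (secant)."""
        return self.optical_bap_peak_dff / self.local_bap_mv

    @property
    def small_signal_sensitivity(self) -> float:
        """%ΔF/F per mV in the small-signal (near-rest) limit."""
        return self.curve.s * self.peak_sensitivity


def calibrate_spine(
    optical_bap_peak_dff: float,
    somatic_ap_mv: float = DEFAULT_AP_MV,
    d_um: float = 0.0,
    lambda_um: float = DEFAULT_LAMBDA_UM,
    curve: SensitivityCurve | None = None,
) -> SpineCalibration:
    """Build a :class:`SpineCalibration` from one spine's bAP measurements."""
    return SpineCalibration(
        distance_um=d_um,
        optical_bap_peak_dff=optical_bap_peak_dff,
        somatic_ap_mv=somatic_ap_mv,
        lambda_um=lambda_um,
        curve=curve or SensitivityCurve(),
    )


def dff_to_mv(amplitude_dff: float, cal: SpineCalibration, method: str = "quadratic") -> float:
    """Convert a %ΔF/F amplitude in this spine to mV.

    ``method="quadratic"`` inverts the full sensitivity curve (positive
    root); ``method="linear"`` divides by the small-signal sensitivity,
    which the quadratic inversion approaches for small amplitudes.
    """
    if amplitude_dff < 0:
        raise ValueError("amplitude must be non-negative")
    if method == "linear":
        return amplitude_dff / cal.small_signal_sensitivity
    y = amplitude_dff / cal.optical_bap_peak_dff
    u = cal.curve.invert(y)
    if u > 1.0 + 1e-9:
        raise ValueError(
            f"amplitude {amplitude_dff:.3g} %ΔF/F exceeds the calibrated range "
            f"(optical bAP peak {cal.optical_bap_peak_dff:.3g} %ΔF/F)"
        )
    return float(u * cal.local_bap_mv)


def voltage_detection_limit(noise: NoiseEstimate, cal: SpineCalibration) -> float:
    """The experiment's voltage resolution: 2.5·σ_noise expressed in mV.

    Detection limits live in the small-signal regime, so the conversion uses
    the small-signal sensitivity directly (2.5σ / s·peak-sensitivity).
    """
    return THRESHOLD_MULT * noise.sigma / cal.small_signal_sensitivity
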