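"""Time-series containers for single-voxel optical and somatic recordings.

Conventions used throughout the package:

* time is in **milliseconds**, sampling interval ``dt`` in ms;
* optical signals are either raw fluorescence (arbitrary counts) or
  fractional change in **percent** ΔF/F;
* somatic voltage is in **mV**.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["OpticalTrace", "SomaticTrace", "FrapTrace"]


@dataclass
class OpticalTrace:
    """A single-voxel fluorescence recording.

    Parameters
    ----------
    samples : ndarray
        Fluorescence values, raw counts or %ΔF/F depending on ``units``.
    dt : float
        Sampling interval in ms (strictly positive).
    units : str
        ``"counts"`` or ``"pct_dff"``.
    label : str
        Trial type: ``"uncaging"``, ``"control"`` or ``"bap"``.
    uncaging_time : float or None
        Time of the uncaging pulse in ms from trace start.
    artifact_window : tuple of float or None
        ``(t0, t1)`` window (ms) occupied by the uncaging artifact.
    """

    samples: np.ndarray
    dt: float
    units: str = "counts"
    label: str = "uncaging"
    uncaging_time: float | None = None
    artifact_window: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise ValueError("sampling interval must be strictly positive")
        if self.samples.ndim != 1:
            raise ValueError("trace samples must be one-dimensional")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms."""
        return np.arange(self.n) * self.dt

    @property
    def duration(self) -> float:
        return self.n * self.dt

    def with_samples(self, samples: np.ndarray, units: str | None = None) -> "OpticalTrace":
        """Copy of this trace with new samples (metadata preserved)."""
        out = replace(self, samples=np.asarray(samples, dtype=float))
        if units is not None:
            out.units = units
        return out

    def index_of(self, t_ms: float) -> int:
        """Nearest sample index for a time in ms."""
        return int(round(t_ms / self.dt))

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"time_ms": self.times, "value": self.samples})
        df.attrs["units"] = self.units
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "OpticalTrace":
        df = pd.read_csv(path)
        t = df["time_ms"].to_numpy()
        dt = float(np.median(np.diff(t)))
        return cls(df["value"].to_numpy(), dt=dt, **kwargs)


@dataclass
class SomaticTrace:
    """Somatic whole-cell voltage recording (mV)."""

    samples: np.ndarray
    dt: float
    spike_time: float | None = None  # ms, peak of the AP if present

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise ValueError("sampling interval must be strictly positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt


@dataclass
class FrapTrace:
    """Fluorescence-recovery-after-photobleaching record.

    ``bleach_time`` marks the end of the bleaching pulse; samples before it
    are the pre-bleach baseline (normalised to ~1).
    """

    samples: np.ndarray
    dt: float
    bleach_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise ValueError("sampling interval must be strictly positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt
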