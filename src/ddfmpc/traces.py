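"""Uniformly sampled time-series containers and spike trains.

All traces are uniformly sampled with an explicit sampling period ``dt``
(milliseconds).  Voltages are in mV, currents in µA (the Connor-Stevens
parameters used here are normalized to a 1 cm² soma, so µA and µA/cm²
coincide).  Traces round-trip through two-column CSV files
(``time_ms,value``), spike trains through one-column CSV files of spike
times in ms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np


def _as_float_array(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"trace values must be 1-D, got shape {arr.shape}")
    return arr


@dataclass
class Trace:
    """A uniformly sampled scalar time series.

    Parameters
    ----------
    values:
        Sample values; ``values[k]`` is the value at ``t0 + k * dt``.
    dt:
        Sampling period in ms (> 0).
    t0:
        Time of the first sample in ms.
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values)
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        """Time spanned from the first to the last sample, in ms."""
        return max(len(self.values) - 1, 0) * self.dt

    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.values))

    def downsample(self, factor: int) -> "Trace":
        """Decimate by keeping every ``factor``-th sample (no filtering)."""
        if int(factor) != factor or factor < 1:
            raise ValueError(f"downsample factor must be an integer >= 1, got {factor}")
        factor = int(factor)
        return dataclasses.replace(
            self, values=self.values[::factor].copy(), dt=self.dt * factor
        )

    def zero_order_hold(self, dt: float, n: int) -> np.ndarray:
        """Resample onto a grid ``t0 + dt * arange(n)`` by holding the most
        recent sample (piecewise-constant interpolation)."""
        t = self.t0 + dt * np.arange(n)
        idx = np.floor((t - self.t0) / self.dt + 1e-9).astype(int)
        idx = np.clip(idx, 0, len(self.values) - 1)
        return self.values[idx]

    def to_csv(self, path, label: str = "value") -> None:
        data = np.column_stack([self.times(), self.values])
        np.savetxt(path, data, delimiter=",", header=f"time_ms,{label}", comments="")

    @classmethod
    def from_csv(cls, path) -> "Trace":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        t, v = data[:, 0], data[:, 1]
        if len(t) > 1:
            dts = np.diff(t)
            dt = float(dts[0])
            if not np.allclose(dts, dt, rtol=1e-6, atol=1e-9):
                raise ValueError(f"{path}: samples are not uniformly spaced")
        else:
            dt = 1.0
        return cls(values=v, dt=dt, t0=float(t[0]))


@dataclass
class VoltageTrace(Trace):
    """Membrane voltage in mV."""

    def to_csv(self, path, label: str = "voltage_mV") -> None:
        super().to_csv(path, label=label)


@dataclass
class CurrentTrace(Trace):
    """Injected or synaptic current in µA."""

    def to_csv(self, path, label: str = "current_uA") -> None:
        super().to_csv(path, label=label)


def downsample(trace: Trace, factor: int) -> Trace:
    """Module-level alias for :meth:`Trace.downsample`."""
    return trace.downsample(factor)


@dataclass
class SpikeTrain:
    """Ordered spike times in ms (strictly increasing)."""

    times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times)
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def within(self, t_start: float, t_end: float) -> np.ndarray:
        """Spike times falling in the closed window [t_start, t_end]."""
        t = self.times
        return t[(t >= t_start) & (t <= t_end)]

    def to_csv(self, path) -> None:
        np.savetxt(path, self.times.reshape(-1, 1), delimiter=",",
                   header="spike_time_ms", comments="")

    @classmethod
    def from_csv(cls, path) -> "SpikeTrain":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=1)
        return cls(times=np.atleast_1d(data))
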