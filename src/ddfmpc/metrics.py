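"""Trajectory and spike-train similarity measures.

Controllers are scored with three measures: mean squared error between the
realized and reference voltage, and the bivariate ISI-distance and
SPIKE-distance between the realized and reference spike trains (Kreuz et
al. definitions).  Both spike-train distances are parameter-free,
time-resolved dissimilarity profiles averaged over the observation
window, lie in [0, 1], and are 0 exactly for identical trains.

Edge correction follows the standard convention: auxiliary spikes are
placed at both window boundaries of each train before the profiles are
evaluated.  A train with no spikes inside the window cannot be scored
meaningfully; against a non-empty train the distance is defined as 1
(maximal dissimilarity), while two empty trains are identical (0).

The profiles are piecewise constant (ISI) or piecewise linear (SPIKE)
between consecutive spikes of the merged pair of trains, so the time
averages are computed exactly, segment by segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traces import SpikeTrain, VoltageTrace

__all__ = ["TrialMetrics", "mse", "isi_distance", "spike_distance", "score"]


@dataclass
class TrialMetrics:
    """Per-trial controller scores."""

    mse: float             # mV²
    isi_distance: float    # dimensionless, [0, 1]
    spike_distance: float  # dimensionless, [0, 1]

    def as_dict(self) -> dict:
        return {"mse": self.mse, "isi_distance": self.isi_distance,
                "spike_distance": self.spike_distance}


def mse(v: VoltageTrace | np.ndarray, v_ref: VoltageTrace | np.ndarray) -> float:
    """Mean squared pointwise difference between two aligned traces (mV²)."""
    a = v.values if isinstance(v, VoltageTrace) else np.asarray(v, dtype=float)
    b = v_ref.values if isinstance(v_ref, VoltageTrace) else np.asarray(v_ref, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if isinstance(v, VoltageTrace) and isinstance(v_ref, VoltageTrace):
        if abs(v.dt - v_ref.dt) > 1e-12:
            raise ValueError("sampling periods differ")
    return float(np.mean((a - b) ** 2))


def _window_times(train: SpikeTrain | np.ndarray, t_start: float,
                  t_end: float) -> np.ndarray:
    t = train.times if isinstance(train, SpikeTrain) else np.asarray(train, dtype=float)
    return t[(t >= t_start) & (t <= t_end)]


def _with_aux(spikes: np.ndarray, t_start: float, t_end: float) -> np.ndarray:
    """Append auxiliary boundary spikes (deduplicated)."""
    out = [spikes]
    if len(spikes) == 0 or spikes[0] > t_start:
        out.insert(0, [t_start])
    if len(spikes) == 0 or spikes[-1] < t_end:
        out.append([t_end])
    return np.concatenate(out)


def _check_window(t_start: float, t_end: float) -> None:
    if not t_end > t_start:
        raise ValueError("empty observation window")


def _empty_case(a: np.ndarray, b: np.ndarray) -> float | None:
    if len(a) == 0 and len(b) == 0:
        return 0.0
    if len(a) == 0 or len(b) == 0:
        return 1.0
    return None


def isi_distance(a: SpikeTrain | np.ndarray, b: SpikeTrain | np.ndarray,
                 t_start: float, t_end: float) -> float:
    """Bivariate ISI-distance: time average of the normalized instantaneous
    interspike-interval mismatch |x1 - x2| / max(x1, x2)."""
    _check_window(t_start, t_end)
    sa = _window_times(a, t_start, t_end)
    sb = _window_times(b, t_start, t_end)
    special = _empty_case(sa, sb)
    if special is not None:
        return special
    ea = _with_aux(sa, t_start, t_end)
    eb = _with_aux(sb, t_start, t_end)
    events = np.unique(np.concatenate([ea, eb]))
    total = 0.0
    for lo, hi in zip(events[:-1], events[1:]):
        mid = 0.5 * (lo + hi)
        x1 = _current_isi(ea, mid)
        x2 = _current_isi(eb, mid)
        ratio = abs(x1 - x2) / max(x1, x2)
        total += ratio * (hi - lo)
    return total / (t_end - t_start)


def _current_isi(spikes: np.ndarray, t: float) -> float:
    """Length of the interspike interval containing time t."""
    k = np.searchsorted(spikes, t) - 1
    k = min(max(k, 0), len(spikes) - 2)
    return spikes[k + 1] - spikes[k]


def spike_distance(a: SpikeTrain | np.ndarray, b: SpikeTrain | np.ndarray,
                   t_start: float, t_end: float) -> float:
    """Bivariate SPIKE-distance: time average of the spike-timing
    dissimilarity profile S(t).

    For each train n, with preceding/following spikes t_P, t_F around t,
    x_P = t - t_P, x_F = t_F - t, x_ISI = t_F - t_P, and nearest-neighbor
    offsets dt_P, dt_F from those spikes to the other train,

        S_n(t) = (dt_P x_F + dt_F x_P) / x_ISI,
        S(t) = (S_1 x_ISI2 + S_2 x_ISI1) / (2 <x_ISI>²),

    with <x_ISI> the mean of the two local interspike intervals.
    """
    _check_window(t_start, t_end)
    sa = _window_times(a, t_start, t_end)
    sb = _window_times(b, t_start, t_end)
    special = _empty_case(sa, sb)
    if special is not None:
        return special
    ea = _with_aux(sa, t_start, t_end)
    eb = _with_aux(sb, t_start, t_end)
    events = np.unique(np.concatenate([ea, eb]))
    total = 0.0
    for lo, hi in zip(events[:-1], events[1:]):
        s_lo = _spike_profile(ea, eb, lo, hi, lo)
        s_hi = _spike_profile(ea, eb, lo, hi, hi)
        total += 0.5 * (s_lo + s_hi) * (hi - lo)  # profile linear in segment
    return total / (t_end - t_start)


def _spike_profile(ea: np.ndarray, eb: np.ndarray, seg_lo: float,
                   seg_hi: float, t: float) -> float:
    """SPIKE-dissimilarity profile at time t inside segment [seg_lo, seg_hi].

    The segment interior determines the bracketing spikes; evaluating at a
    segment endpoint uses that segment's bracketing (one-sided limit).
    """
    mid = 0.5 * (seg_lo + seg_hi)
    s1, isi1 = _one_sided(ea, eb, mid, t)
    s2, isi2 = _one_sided(eb, ea, mid, t)
    mean_isi = 0.5 * (isi1 + isi2)
    if mean_isi == 0.0:
        return 0.0
    return (s1 * isi2 + s2 * isi1) / (2.0 * mean_isi ** 2)


def _one_sided(train: np.ndarray, other: np.ndarray, mid: float,
               t: float) -> tuple[float, float]:
    k = np.searchsorted(train, mid) - 1
    k = min(max(k, 0), len(train) - 2)
    t_p, t_f = train[k], train[k + 1]
    isi = t_f - t_p
    dt_p = np.min(np.abs(other - t_p))
    dt_f = np.min(np.abs(other - t_f))
    x_p = t - t_p
    x_f = t_f - t
    if isi == 0.0:
        return 0.0, 0.0
    return (dt_p * x_f + dt_f * x_p) / isi, isi


def score(v: VoltageTrace, reference: VoltageTrace,
          threshold: float = 30.0) -> TrialMetrics:
    """All three measures between a realized trace and its reference."""
    from .neuron_sim import detect_spikes

    t_start = reference.t0
    # a single-sample trace still spans one sampling period
    t_end = reference.t0 + max(reference.duration, reference.dt)
    sa = detect_spikes(v, threshold)
    sb = detect_spikes(reference, threshold)
    return TrialMetrics(
        mse=mse(v, reference),
        isi_distance=isi_distance(sa, sb, t_start, t_end),
        spike_distance=spike_distance(sa, sb, t_start, t_end),
    )
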