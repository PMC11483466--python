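"""Closed-loop control of the simulated neuron.

The main controller is receding-horizon nonlinear MPC: at every control
period the forecaster (an :class:`~ddfmpc.ddf.RBFNModel`) is rolled out
``T`` steps ahead from the latest *measured* voltage, and the injected
currents over the horizon are optimized to minimize

    s e_T² + Σ_{n=0}^{T-1} [ q e_{n+1}² + r ΔI_{n+1}² ],   |I_n| ≤ I_max,

where ``e_n`` is the tracking error against the reference trajectory and
``ΔI`` penalizes input fluctuation.  Only the first optimized input is
applied; the optimization repeats each period with the embedding history
refreshed from plant measurements.

Baselines: proportional feedback (voltage-clamp style), open-loop replay
of a stored current, and open-loop rectangular pulses for spike-train
references.  Reference trajectories for spike-train control are built by
embedding the neuron's mean spike waveform into a constant sub-threshold
series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import _kernels
from .ddf import RBFNModel
from .metrics import TrialMetrics, score
from .neuron_sim import GatingState, NeuronParams, detect_spikes, resting_state
from .traces import CurrentTrace, SpikeTrain, VoltageTrace

__all__ = [
    "MPCConfig", "ControlResult", "CSPlant", "DDFPlant", "mpc_step",
    "run_mpc", "proportional_control", "open_loop_replay", "pulse_control",
    "calibrate_pulse_amplitude", "spikes_to_reference",
    "extract_mean_waveform",
]


@dataclass(frozen=True)
class MPCConfig:
    """Receding-horizon controller settings."""

    horizon: int = 5        # T, steps
    s: float = 1.0          # terminal-error weight
    q: float = 1.0          # state-error weight
    r: float = 0.01         # input-change weight
    i_max: float = 100.0    # µA, symmetric box bound
    dt: float = 0.1         # control period, ms

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if min(self.s, self.q, self.r) < 0:
            raise ValueError("cost weights must be non-negative")
        if self.i_max <= 0:
            raise ValueError("input bound must be positive")


@dataclass
class ControlResult:
    """Realized voltage, applied input, reference and per-trial metrics."""

    voltage: VoltageTrace
    current: CurrentTrace
    reference: VoltageTrace
    metrics: TrialMetrics
    info: dict = field(default_factory=dict)


class CSPlant:
    """The true Connor-Stevens neuron, advanced one control period at a time.

    The controller's input is zero-order-held across the control period
    and integrated at the fine step ``h``; the (unknown to the
    controller) noise current is pre-generated on the fine grid.
    """

    def __init__(self, params: NeuronParams, dt: float = 0.1, h: float = 0.02,
                 noise: CurrentTrace | None = None,
                 v0: float | None = None, gating0: GatingState | None = None):
        self.params = params
        self.dt = dt
        self.h = h
        self.n_sub = int(round(dt / h))
        if abs(self.n_sub * h - dt) > 1e-9:
            raise ValueError("control period must be a multiple of h")
        if v0 is None or gating0 is None:
            v_rest, g_rest = resting_state(params, h=h)
            v0 = v_rest if v0 is None else v0
            gating0 = g_rest if gating0 is None else gating0
        self.v = float(v0)
        self.gating = gating0.as_array()
        self._noise = noise.values if noise is not None else None
        self._pos = 0  # fine-grid position

    def step(self, i_inj: float) -> float:
        """Apply ``i_inj`` for one control period; return the measured voltage."""
        if self._noise is None:
            i_tot = np.full(self.n_sub, i_inj)
        else:
            chunk = self._noise[self._pos: self._pos + self.n_sub]
            if len(chunk) < self.n_sub:
                raise ValueError("noise trace exhausted before trial end")
            i_tot = i_inj + chunk
        V, G, blow = _kernels.cs_integrate(
            self.v, self.gating, i_tot, self.h,
            *self.params._conductance_args())
        if blow >= 0:
            from .neuron_sim import IntegrationError
            raise IntegrationError(
                f"plant integration failed at fine step {self._pos + blow}")
        self.v = float(V[-1])
        self.gating = G[-1]
        self._pos += self.n_sub
        return self.v


class DDFPlant:
    """The forecaster itself used as the plant (model-matched control)."""

    def __init__(self, model: RBFNModel, v0: float, i0: float = 0.0):
        self.model = model
        self.dt = model.dt
        L = model.embedding.history
        self._hist = [float(v0)] * (L + 1)
        self._i_prev = i0

    @property
    def v(self) -> float:
        return self._hist[-1]

    def step(self, i_inj: float) -> float:
        from .ddf import predict_step

        spec = self.model.embedding
        S = np.array([self._hist[-1 - d * spec.delay]
                      for d in range(spec.dimension)])
        v_next = predict_step(self.model, S, self._i_prev, i_inj)
        self._hist.append(v_next)
        self._hist = self._hist[-(spec.history + 1):] if spec.history else [v_next]
        self._i_prev = i_inj
        return v_next


def _solve_horizon(model: RBFNModel, v_hist: np.ndarray, i_prev: float,
                   ref_window: np.ndarray, cfg: MPCConfig,
                   warm: np.ndarray | None = None) -> tuple[np.ndarray, bool]:
    """Solve the T-step horizon problem; returns (inputs, solver_ok).

    Falls back to holding the previous input (clamped) if the solver fails
    or does not improve on it; the hold sequence is always evaluated, so
    the returned plan never costs more than holding.
    """
    T = cfg.horizon
    hold = np.full(T, np.clip(i_prev, -cfg.i_max, cfg.i_max))
    args = (v_hist, float(i_prev), ref_window, model.centers, model.weights,
            model.alpha, model.R, model.embedding.delay,
            cfg.s, cfg.q, cfg.r)
    x0 = hold if warm is None else np.clip(warm, -cfg.i_max, cfg.i_max)
    try:
        res = minimize(_kernels.mpc_cost_grad, x0, args=args, jac=True,
                       method="L-BFGS-B",
                       bounds=[(-cfg.i_max, cfg.i_max)] * T,
                       options={"maxiter": 100, "ftol": 1e-12, "gtol": 1e-10})
        x = np.clip(res.x, -cfg.i_max, cfg.i_max)
        if not np.all(np.isfinite(x)):
            x = hold
    except Exception:
        x = hold
    cost_x, _ = _kernels.mpc_cost_grad(x, *args)
    cost_hold, _ = _kernels.mpc_cost_grad(hold, *args)
    if cost_hold < cost_x:  # never return a plan worse than holding
        return hold, False
    return x, True


def mpc_step(model: RBFNModel, v_history, i_prev: float, ref_window,
             cfg: MPCConfig, warm=None) -> float:
    """One receding-horizon solve; returns only the first optimized input.

    ``v_history`` must hold the most recent measured voltages, oldest
    first, with exactly ``(D_e - 1) tau + 1`` entries (the current
    measurement last).  ``ref_window`` holds the next ``horizon``
    reference voltages.
    """
    v_hist = np.asarray(v_history, dtype=float)
    if len(v_hist) != model.embedding.history + 1:
        raise ValueError(
            f"history must have {model.embedding.history + 1} samples")
    if abs(i_prev) > cfg.i_max:
        raise ValueError("previous input violates the box bound")
    ref_window = np.asarray(ref_window, dtype=float)
    if len(ref_window) != cfg.horizon:
        raise ValueError("reference window must match the horizon")
    x, _ = _solve_horizon(model, v_hist, i_prev, ref_window, cfg,
                          None if warm is None else np.asarray(warm, dtype=float))
    return float(x[0])


def _finalize(v_meas: list, i_applied: list, ref: VoltageTrace,
              info: dict) -> ControlResult:
    voltage = VoltageTrace(values=np.array(v_meas), dt=ref.dt,
                           t0=ref.t0)
    current = CurrentTrace(values=np.array(i_applied), dt=ref.dt, t0=ref.t0)
    return ControlResult(voltage=voltage, current=current, reference=ref,
                         metrics=score(voltage, ref), info=info)


def run_mpc(plant, model: RBFNModel, ref: VoltageTrace, cfg: MPCConfig,
            i0: float = 0.0) -> ControlResult:
    """Receding-horizon control loop against a reference trajectory.

    At every control period the plant voltage is measured, the embedding
    history is refreshed with the measurement (never the model's own
    prediction), one horizon problem is solved warm-started from the
    previous solution, and the first optimized input is applied for one
    period.  ``ref.values[k]`` is the target for the measurement taken
    after control step k.
    """
    K = len(ref)
    if K == 0:
        empty_v = VoltageTrace(values=[], dt=ref.dt)
        empty_i = CurrentTrace(values=[], dt=ref.dt)
        return ControlResult(voltage=empty_v, current=empty_i, reference=ref,
                             metrics=TrialMetrics(0.0, 0.0, 0.0),
                             info={"controller": "mpc", "empty": True})
    L = model.embedding.history
    v_hist = np.full(L + 1, plant.v)
    i_prev = float(i0)
    warm = None
    n_fallback = 0
    v_meas, i_applied = [], []
    ref_vals = ref.values
    for k in range(K):
        hi = min(k + cfg.horizon, K)
        window = ref_vals[k:hi]
        if len(window) < cfg.horizon:  # pad final partial horizon
            window = np.concatenate(
                [window, np.full(cfg.horizon - len(window), ref_vals[-1])])
        x, ok = _solve_horizon(model, v_hist, i_prev, window, cfg, warm)
        if not ok:
            n_fallback += 1
        i_next = float(x[0])
        v = plant.step(i_next)
        v_meas.append(v)
        i_applied.append(i_next)
        v_hist = np.append(v_hist[1:], v)
        i_prev = i_next
        warm = np.append(x[1:], x[-1])
    return _finalize(v_meas, i_applied, ref,
                     {"controller": "mpc", "solver_fallbacks": n_fallback})


def proportional_control(plant, ref: VoltageTrace, kp: float = -2.0,
                         clamp: float = 100.0) -> ControlResult:
    """Voltage-clamp style feedback: I = clip(Kp (V - V_ref), ±clamp)."""
    v = plant.v
    v_meas, i_applied = [], []
    for target in ref.values:
        i = float(np.clip(kp * (v - target), -clamp, clamp))
        v = plant.step(i)
        v_meas.append(v)
        i_applied.append(i)
    return _finalize(v_meas, i_applied, ref, {"controller": "proportional",
                                              "kp": kp})


def open_loop_replay(plant, i_stored: CurrentTrace,
                     ref: VoltageTrace) -> ControlResult:
    """Apply a stored current with no feedback; score against ``ref``."""
    if len(i_stored) < len(ref):
        raise ValueError("stored current does not cover the trial")
    v_meas = [plant.step(float(i)) for i in i_stored.values[:len(ref)]]
    return _finalize(v_meas, list(i_stored.values[:len(ref)]), ref,
                     {"controller": "open_loop"})


def pulse_train_current(spike_times, width: float, amplitude: float,
                        duration: float, dt: float) -> CurrentTrace:
    """Rectangular pulses of the given width starting at each spike time."""
    times = np.asarray(spike_times, dtype=float)
    if np.any(np.diff(times) < width):
        raise ValueError("pulses overlap")
    n = int(round(duration / dt)) + 1
    values = np.zeros(n)
    for t in times:
        lo = int(round(t / dt))
        hi = min(int(round((t + width) / dt)), n)
        values[lo:hi] = amplitude
    return CurrentTrace(values=values, dt=dt)


def pulse_control(plant, spike_times, width: float = 2.0,
                  amplitude: float = 50.0,
                  ref: VoltageTrace | None = None) -> ControlResult:
    """Open-loop pulse stimulation at the requested spike times.

    The amplitude is a per-neuron-type constant obtained from
    :func:`calibrate_pulse_amplitude` (one spike per pulse on the
    noiseless plant).  ``ref`` (if given) is used only for scoring.
    """
    duration = ref.duration if ref is not None else (
        (max(spike_times) + 50.0) if len(spike_times) else 100.0)
    current = pulse_train_current(spike_times, width, amplitude,
                                  duration, plant.dt)
    n = len(ref) if ref is not None else len(current)
    v_meas = [plant.step(float(i)) for i in current.values[:n]]
    voltage = VoltageTrace(values=np.array(v_meas), dt=plant.dt)
    if ref is None:
        ref = voltage
    return _finalize(v_meas, list(current.values[:n]), ref,
                     {"controller": "pulse", "amplitude": amplitude,
                      "width": width})


def calibrate_pulse_amplitude(params: NeuronParams, width: float = 2.0,
                              amplitudes=None, dt: float = 0.1,
                              h: float = 0.02) -> float:
    """Smallest pulse amplitude that reliably elicits exactly one spike.

    A single pulse is applied to the noiseless plant at rest; the sweep
    returns the smallest amplitude producing exactly one spike in a 50 ms
    window, with the next grid point also producing exactly one (so the
    choice is not a knife-edge).
    """
    if amplitudes is None:
        amplitudes = np.arange(5.0, 100.1, 5.0)
    counts = {}

    def n_spikes(amp: float) -> int:
        plant = CSPlant(params, dt=dt, h=h)
        current = pulse_train_current([5.0], width, amp, 50.0, dt)
        v = [plant.step(float(i)) for i in current.values]
        return len(detect_spikes(VoltageTrace(values=np.array(v), dt=dt)))

    amplitudes = list(amplitudes)
    for k, amp in enumerate(amplitudes):
        counts[amp] = n_spikes(amp)
        if counts[amp] == 1:
            if k + 1 == len(amplitudes) or n_spikes(amplitudes[k + 1]) == 1:
                return float(amp)
    raise ValueError("no amplitude in the sweep elicits exactly one spike")


def extract_mean_waveform(v: VoltageTrace, spikes: SpikeTrain,
                          window: float = 10.0) -> np.ndarray:
    """Mean spike-aligned voltage snippet (±window ms around each spike).

    Spikes whose window does not fit inside the trace are skipped; at
    least one complete snippet is required.
    """
    if len(spikes) == 0:
        raise ValueError("no spikes to average")
    half = int(round(window / v.dt))
    snippets = []
    for t in spikes.times:
        k = int(round((t - v.t0) / v.dt))
        if k - half < 0 or k + half + 1 > len(v):
            continue
        snippets.append(v.values[k - half: k + half + 1])
    if not snippets:
        raise ValueError("no spike window fits inside the trace")
    return np.mean(snippets, axis=0)


def spikes_to_reference(spike_times, waveform: np.ndarray,
                        baseline: float = -65.0, duration: float = 1000.0,
                        dt: float = 0.1) -> VoltageTrace:
    """Reference trajectory with the mean spike waveform at requested times.

    The waveform is pasted into a constant sub-threshold series so that
    its peak lands exactly on each requested spike time.
    """
    times = np.asarray(spike_times, dtype=float)
    waveform = np.asarray(waveform, dtype=float)
    peak = int(np.argmax(waveform))
    n = int(round(duration / dt)) + 1
    values = np.full(n, float(baseline))
    support = len(waveform) * dt
    if len(times) > 1 and np.any(np.diff(times) <= support):
        raise ValueError("spikes closer than the waveform support overlap")
    for t in times:
        k = int(round(t / dt))
        lo, hi = k - peak, k - peak + len(waveform)
        wlo, whi = max(0, -lo), len(waveform) - max(0, hi - n)
        values[max(lo, 0): min(hi, n)] = waveform[wlo:whi]
    return VoltageTrace(values=values, dt=dt)
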