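"""Connor-Stevens neuron simulation and stimulus generation.

The plant is the Connor-Stevens (CS) conductance model: Hodgkin-Huxley
sodium and delayed-rectifier potassium currents plus a transient A-type
potassium current and a leak, normalized to a 1 cm² soma so that
capacitance is in µF, conductances in mS, currents in µA and voltage in
mV.  Two parameterizations are provided:

* Type-I excitability (``g_A = 47.7 mS``, ``E_l = -22 mV``): firing rate
  rises continuously from zero as the input current crosses threshold
  (saddle-node bifurcation).
* Type-II excitability (``g_A = 0``, ``E_l = -72.8 mV``): the firing rate
  jumps discontinuously at threshold (Andronov-Hopf bifurcation).

Stimuli: chaotic currents from the time-scaled Lorenz-63 system (the x(t)
component scaled by an amplitude), and synaptic background noise built
from excitatory and inhibitory Poisson trains convolved with an alpha
kernel and scaled to a target signal-to-noise ratio.

Integration is fixed-step RK4 (default h = 0.02 ms) with zero-order-held
input currents.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, asdict

import numpy as np

from . import _kernels
from .traces import CurrentTrace, SpikeTrain, VoltageTrace, downsample  # noqa: F401

__all__ = [
    "ExcitabilityType", "NeuronParams", "GatingState", "IntegrationError",
    "steady_gating", "resting_state", "simulate_cs", "detect_spikes",
    "fi_curve", "make_lorenz_current", "make_noise_current", "downsample",
]


class ExcitabilityType(enum.Enum):
    TYPE_I = 1
    TYPE_II = 2


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""


@dataclass(frozen=True)
class NeuronParams:
    """Connor-Stevens parameters (1 cm² soma normalization)."""

    C: float = 1.0        # µF
    g_na: float = 120.0   # mS
    g_k: float = 20.0     # mS
    g_a: float = 47.7     # mS
    g_l: float = 0.3      # mS
    e_na: float = 50.0    # mV
    e_k: float = -77.0    # mV
    e_a: float = -80.0    # mV
    e_l: float = -22.0    # mV
    excitability_type: ExcitabilityType = ExcitabilityType.TYPE_I

    def __post_init__(self) -> None:
        for name in ("g_na", "g_k", "g_a", "g_l"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.excitability_type is ExcitabilityType.TYPE_I:
            if not (self.g_a == 47.7 and self.e_l == -22.0):
                raise ValueError("Type-I requires g_a=47.7 mS and e_l=-22 mV")
        else:
            if not (self.g_a == 0.0 and self.e_l == -72.8):
                raise ValueError("Type-II requires g_a=0 mS and e_l=-72.8 mV")

    @classmethod
    def type_i(cls) -> "NeuronParams":
        return cls()

    @classmethod
    def type_ii(cls) -> "NeuronParams":
        return cls(g_a=0.0, e_l=-72.8,
                   excitability_type=ExcitabilityType.TYPE_II)

    def _conductance_args(self) -> tuple:
        return (self.C, self.g_na, self.g_k, self.g_a, self.g_l,
                self.e_na, self.e_k, self.e_a, self.e_l)

    def to_json(self, path) -> None:
        doc = asdict(self)
        doc["excitability_type"] = self.excitability_type.name
        with open(path, "w") as fp:
            json.dump(doc, fp, indent=2)

    @classmethod
    def from_json(cls, path) -> "NeuronParams":
        with open(path) as fp:
            doc = json.load(fp)
        doc["excitability_type"] = ExcitabilityType[doc["excitability_type"]]
        return cls(**doc)


@dataclass
class GatingState:
    """Channel activation (m, n, a) and inactivation (h, b) variables."""

    m: float
    h: float
    n: float
    a: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.array([self.m, self.h, self.n, self.a, self.b])


def steady_gating(v: float) -> GatingState:
    """Gating steady state at a fixed voltage (rate-function fixed point)."""
    am = 0.38 * _vtrap_py(v + 34.7, 10.0)
    bm = 15.2 * np.exp(-0.0556 * (v + 59.7))
    ah = 0.266 * np.exp(-0.05 * (v + 53.0))
    bh = 3.8 / (1.0 + np.exp(-0.1 * (v + 23.0)))
    an = 0.02 * _vtrap_py(v + 50.7, 10.0)
    bn = 0.25 * np.exp(-0.0125 * (v + 60.7))
    a_inf = (0.0761 * np.exp((v + 99.22) / 31.84)
             / (1.0 + np.exp((v + 6.17) / 28.93))) ** (1.0 / 3.0)
    b_inf = (1.0 / (1.0 + np.exp((v + 58.3) / 14.54))) ** 4
    return GatingState(m=am / (am + bm), h=ah / (ah + bh),
                       n=an / (an + bn), a=a_inf, b=b_inf)


def _vtrap_py(x: float, scale: float) -> float:
    if abs(x) < 1e-7:
        return scale
    return x / (1.0 - np.exp(-x / scale))


def simulate_cs(params: NeuronParams,
                i_inj: CurrentTrace | None,
                i_noise: CurrentTrace | None,
                step: float = 0.02,
                duration: float | None = None,
                v0: float | None = None,
                gating0: GatingState | None = None,
                ) -> tuple[VoltageTrace, dict[str, np.ndarray]]:
    """Integrate the CS model under injected plus noise current.

    Input traces are zero-order-held between their samples.  Returns the
    voltage on the integration grid and the gating trajectories (keys
    ``m, h, n, a, b``).  Raises :class:`IntegrationError` naming the time
    of blow-up if the state becomes non-finite.
    """
    if step <= 0:
        raise ValueError("integration step must be positive")
    if duration is None:
        ref = i_inj if i_inj is not None else i_noise
        if ref is None:
            raise ValueError("duration required when no input trace is given")
        duration = ref.duration
    n_steps = int(round(duration / step))
    for trace in (i_inj, i_noise):
        if trace is not None and trace.t0 + trace.duration < duration - 1e-9:
            raise ValueError("input trace does not cover the simulation window")
    i_total = np.zeros(n_steps)
    if i_inj is not None:
        i_total += i_inj.zero_order_hold(step, n_steps)
    if i_noise is not None:
        i_total += i_noise.zero_order_hold(step, n_steps)
    if v0 is None or gating0 is None:
        v_rest, g_rest = resting_state(params, h=step)
        v0 = v_rest if v0 is None else v0
        gating0 = g_rest if gating0 is None else gating0
    V, G, blow = _kernels.cs_integrate(
        float(v0), gating0.as_array(), i_total, step, *params._conductance_args())
    if blow >= 0:
        raise IntegrationError(
            f"non-finite state at t = {blow * step:.3f} ms")
    gating = {name: G[:, k] for k, name in enumerate("mhnab")}
    return VoltageTrace(values=V, dt=step), gating


_REST_CACHE: dict[tuple, tuple[float, GatingState]] = {}


def resting_state(params: NeuronParams, relax: float = 500.0,
                  h: float = 0.02) -> tuple[float, GatingState]:
    """Resting equilibrium, found by relaxing the model with zero input.

    The model is integrated for ``relax`` ms from a nominal holding
    potential with gates at their steady state; the endpoint is returned
    (and cached per parameter set).
    """
    key = (params._conductance_args(), relax, h)
    if key in _REST_CACHE:
        return _REST_CACHE[key]
    v_start = -72.0
    g0 = steady_gating(v_start)
    n_steps = int(round(relax / h))
    V, G, blow = _kernels.cs_integrate(
        v_start, g0.as_array(), np.zeros(n_steps), h,
        *params._conductance_args())
    if blow >= 0:
        raise IntegrationError("relaxation to rest diverged")
    g = GatingState(*G[-1])
    result = (float(V[-1]), g)
    _REST_CACHE[key] = result
    return result


def detect_spikes(v: VoltageTrace, threshold: float = 30.0) -> SpikeTrain:
    """Spike times from upward threshold crossings.

    A spike is recorded at the first sample where the voltage is at or
    above ``threshold`` while the previous sample was below it.
    """
    x = v.values
    up = (x[1:] >= threshold) & (x[:-1] < threshold)
    idx = np.nonzero(up)[0] + 1
    if len(x) > 0 and x[0] >= threshold:
        idx = np.concatenate([[0], idx])
    return SpikeTrain(times=v.t0 + idx * v.dt)


def step_current(amplitude: float, duration: float, dt: float,
                 onset: float = 0.0) -> CurrentTrace:
    """Rectangular step of the given amplitude starting at ``onset``."""
    n = int(round(duration / dt)) + 1
    values = np.zeros(n)
    values[int(round(onset / dt)):] = amplitude
    return CurrentTrace(values=values, dt=dt)


def fi_curve(params: NeuronParams, amplitudes, step_duration: float = 300.0,
             step: float = 0.02, discard: float = 100.0) -> np.ndarray:
    """Steady-state firing rate (Hz) versus step-current amplitude, zero noise.

    Spikes in the first ``discard`` ms of the step are excluded so that a
    single transient spike at step onset (common just below the Type-II
    firing threshold, where the rest state is still stable) does not
    register as sustained firing; the rate is the spike count in the
    remaining window divided by its length.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    if np.any(np.diff(amplitudes) < 0):
        raise ValueError("amplitudes must be sorted ascending")
    if not 0 <= discard < step_duration:
        raise ValueError("discard window must lie within the step")
    rates = np.empty(len(amplitudes))
    v0, g0 = resting_state(params, h=step)
    for k, amp in enumerate(amplitudes):
        stim = step_current(amp, step_duration, dt=step)
        v, _ = simulate_cs(params, stim, None, step=step,
                           duration=step_duration, v0=v0, gating0=g0)
        n_sustained = np.sum(detect_spikes(v).times >= discard)
        rates[k] = n_sustained / (step_duration - discard) * 1000.0
    return rates


def make_lorenz_current(tau: float = 20.0, amplitude: float = 1.8,
                        duration: float = 1000.0, dt: float = 0.02,
                        x0: float = 1.0, y0: float = 1.0, z0: float = 1.0,
                        sigma: float = 10.0, rho: float = 28.0,
                        beta: float = 8.0 / 3.0,
                        burn_in: float = 1000.0) -> CurrentTrace:
    """Chaotic injected current from the time-scaled Lorenz-63 system.

    The system ``tau * dx/dt = sigma (y - x)`` (and cyclic) is integrated
    with time measured in ms; the output is ``amplitude * x(t)`` sampled
    every ``dt``.  A burn-in of ``burn_in`` native Lorenz time units is
    discarded first so the trajectory starts on the attractor (the origin,
    a fixed point, is left untouched).
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    state = np.array([x0, y0, z0], dtype=float)
    if burn_in > 0 and np.any(state != 0.0):
        # burn-in runs in native Lorenz time (tau = 1) at a fine fixed step
        h_burn = 0.005
        _, state = _kernels.lorenz_integrate(
            state, int(round(burn_in / h_burn)), h_burn, 1.0, sigma, rho, beta)
    n = int(round(duration / dt))
    x, _ = _kernels.lorenz_integrate(state, n, dt, tau, sigma, rho, beta)
    # n + 1 samples: the trace covers [0, duration] inclusive
    return CurrentTrace(values=amplitude * x, dt=dt)


def alpha_kernel(decay: float, dt: float, support: float | None = None) -> np.ndarray:
    """Peak-normalized alpha function (t/tau) exp(1 - t/tau), t >= 0."""
    if support is None:
        support = 10.0 * decay
    t = np.arange(0.0, support, dt)
    return (t / decay) * np.exp(1.0 - t / decay)


def make_noise_current(rate_exc: float = 20.0, rate_inh: float = 20.0,
                       alpha_decay: float = 10.0,
                       duration: float = 1000.0, dt: float = 0.02,
                       reference: CurrentTrace | None = None,
                       target_snr: float = 5.0,
                       seed: int = 0) -> CurrentTrace:
    """Synaptic background noise from Poisson inputs.

    Excitatory and inhibitory Poisson spike trains (default 20 Hz each) are
    convolved with a peak-normalized alpha kernel (decay ``alpha_decay``
    ms); the inhibitory contribution is negated, the two are summed, and
    the result is rescaled so that ``std(reference) / std(noise) ==
    target_snr``.  Deterministic given ``seed``.
    """
    if rate_exc < 0 or rate_inh < 0:
        raise ValueError("Poisson rates must be non-negative")
    if target_snr <= 0:
        raise ValueError("target_snr must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt)) + 1
    kernel = alpha_kernel(alpha_decay, dt)
    noise = np.zeros(n)
    for rate, sign in ((rate_exc, 1.0), (rate_inh, -1.0)):
        events = rng.random(n) < rate * dt * 1e-3  # rate in Hz, dt in ms
        if events.any():
            noise += sign * np.convolve(events.astype(float), kernel)[:n]
    if noise.any():
        if reference is None:
            raise ValueError("a reference trace is required for SNR scaling")
        ref_std = float(np.std(reference.values))
        if ref_std == 0.0:
            raise ValueError("reference trace has zero variance; cannot set SNR")
        noise *= ref_std / (target_snr * float(np.std(noise)))
    return CurrentTrace(values=noise, dt=dt)
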