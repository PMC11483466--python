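"""End-to-end experiment drivers.

Three end-to-end experiments:

* **homogeneous** -- each neuron type tracks a reference trajectory it
  previously produced (chaotic stimulus + synaptic noise), comparing MPC
  against open-loop replay of the reference-generating current;
* **heterogeneous** -- the reference comes from the *other* neuron type
  (can a Type-I neuron be made to spike like a Type-II neuron?), again
  MPC versus open-loop replay;
* **spike-train** -- an arbitrary list of requested spike times is turned
  into a voltage reference by embedding the mean spike waveform in a
  sub-threshold baseline, then tracked with MPC, proportional feedback,
  and calibrated open-loop current pulses.

Every stochastic component is seeded from the experiment seed, so a run
is reproducible bitwise from its config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .control import (
    CSPlant,
    MPCConfig,
    calibrate_pulse_amplitude,
    extract_mean_waveform,
    open_loop_replay,
    proportional_control,
    pulse_control,
    run_mpc,
    spikes_to_reference,
)
from .ddf import EmbeddingSpec, RBFNModel, select_embedding_dim, train_ddf
from .neuron_sim import (
    NeuronParams,
    detect_spikes,
    make_lorenz_current,
    make_noise_current,
    simulate_cs,
)
from .traces import CurrentTrace, VoltageTrace

__all__ = [
    "ExperimentConfig", "LORENZ_AMPLITUDE", "train_pipeline",
    "make_reference", "run_homogeneous", "run_heterogeneous",
    "run_spike_train", "neuron_params",
]

#: chaotic-stimulus amplitude per neuron type (µA per unit Lorenz x)
LORENZ_AMPLITUDE = {"type_i": 1.8, "type_ii": 0.5}


def neuron_params(neuron_type: str) -> NeuronParams:
    if neuron_type == "type_i":
        return NeuronParams.type_i()
    if neuron_type == "type_ii":
        return NeuronParams.type_ii()
    raise ValueError(f"unknown neuron type {neuron_type!r}")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    plant_type: str = "type_i"
    reference_type: str = "type_i"
    n_trials: int = 10
    duration: float = 500.0          # ms per trial
    train_duration: float = 5000.0   # ms of training data
    lorenz_tau: float = 20.0
    noise_rate: float = 20.0         # Hz, each of exc / inh
    snr: float = 5.0
    seed: int = 0
    sim_step: float = 0.02           # ms, plant integration step
    control_dt: float = 0.1          # ms, sampling / control period
    n_centers: int = 50
    R: float = 0.01
    mpc: MPCConfig = field(default_factory=MPCConfig)
    kp: float = -2.0
    pulse_width: float = 2.0
    noisy: bool = True

    @property
    def downsample_factor(self) -> int:
        return int(round(self.control_dt / self.sim_step))

    def to_json(self, path) -> None:
        doc = asdict(self)
        with open(path, "w") as fp:
            json.dump(doc, fp, indent=2)

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        with open(path) as fp:
            doc = json.load(fp)
        doc["mpc"] = MPCConfig(**doc["mpc"])
        return cls(**doc)

    def digest(self) -> str:
        return hashlib.sha1(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def _lorenz_ic(rng: np.random.Generator) -> dict:
    """A randomized pre-burn-in initial condition near the attractor."""
    return {"x0": float(rng.uniform(-10, 10)),
            "y0": float(rng.uniform(-10, 10)),
            "z0": float(rng.uniform(10, 30))}


def _training_record(cfg: ExperimentConfig, neuron_type: str, seed: int
                     ) -> tuple[VoltageTrace, CurrentTrace]:
    """Simulate one training recording, downsampled to the control rate."""
    params = neuron_params(neuron_type)
    rng = np.random.default_rng(seed)
    lor = make_lorenz_current(tau=cfg.lorenz_tau,
                              amplitude=LORENZ_AMPLITUDE[neuron_type],
                              duration=cfg.train_duration, dt=cfg.sim_step,
                              **_lorenz_ic(rng))
    noise = None
    if cfg.noisy:
        noise = make_noise_current(rate_exc=cfg.noise_rate,
                                   rate_inh=cfg.noise_rate,
                                   duration=cfg.train_duration,
                                   dt=cfg.sim_step, reference=lor,
                                   target_snr=cfg.snr,
                                   seed=int(rng.integers(2 ** 31)))
    v, _ = simulate_cs(params, lor, noise, step=cfg.sim_step,
                       duration=cfg.train_duration)
    f = cfg.downsample_factor
    return v.downsample(f), lor.downsample(f)


def train_pipeline(cfg: ExperimentConfig, neuron_types=("type_i", "type_ii"),
                   candidate_dims=range(1, 11), select_dim: bool = True,
                   ) -> dict[str, RBFNModel]:
    """Simulate training data and fit one forecaster per neuron type.

    Training recipe: chaotic stimulus plus SNR-scaled synaptic
    noise, downsampling to the control rate, simplex selection of the
    embedding dimension (delay 1), k-means centers, ridge regression with
    contiguous 10-fold cross-validation of the penalty.
    """
    models = {}
    for k, neuron_type in enumerate(neuron_types):
        v, i = _training_record(cfg, neuron_type, seed=cfg.seed + 1000 * k)
        if select_dim:
            dim = select_embedding_dim(v, candidate_dims, delay=1)
        else:
            dim = 2
        spec = EmbeddingSpec(dimension=dim, delay=1)
        model = train_ddf(v, i, n_centers=cfg.n_centers, R=cfg.R,
                          spec=spec, seed=cfg.seed)
        model.metadata.update({"neuron_type": neuron_type,
                               "config": cfg.digest()})
        models[neuron_type] = model
    return models


def make_reference(cfg: ExperimentConfig, neuron_type: str, seed: int
                   ) -> tuple[VoltageTrace, CurrentTrace]:
    """One reference trial: simulate the neuron under a fresh chaotic
    current (and noise if configured); return the realized voltage at the
    control rate (first sample dropped, so values align with control-step
    measurements) and the injected current at the control rate.

    The chaotic current is held at the control rate (zero-order hold)
    during the simulation, exactly as a controller would apply it, so a
    noiseless open-loop replay of the returned current reproduces the
    reference trajectory identically.
    """
    params = neuron_params(neuron_type)
    rng = np.random.default_rng(seed)
    lor = make_lorenz_current(tau=cfg.lorenz_tau,
                              amplitude=LORENZ_AMPLITUDE[neuron_type],
                              duration=cfg.duration + cfg.control_dt,
                              dt=cfg.sim_step, **_lorenz_ic(rng))
    i_ctrl = lor.downsample(cfg.downsample_factor)
    noise = None
    if cfg.noisy:
        noise = make_noise_current(rate_exc=cfg.noise_rate,
                                   rate_inh=cfg.noise_rate,
                                   duration=cfg.duration + cfg.control_dt,
                                   dt=cfg.sim_step, reference=lor,
                                   target_snr=cfg.snr,
                                   seed=int(rng.integers(2 ** 31)))
    v, _ = simulate_cs(params, i_ctrl, noise, step=cfg.sim_step,
                       duration=cfg.duration)
    v10 = v.downsample(cfg.downsample_factor)
    ref = VoltageTrace(values=v10.values[1:], dt=cfg.control_dt,
                       t0=cfg.control_dt)
    return ref, i_ctrl


def _fresh_plant(cfg: ExperimentConfig, neuron_type: str, reference_current,
                 seed: int) -> CSPlant:
    params = neuron_params(neuron_type)
    noise = None
    if cfg.noisy:
        noise = make_noise_current(rate_exc=cfg.noise_rate,
                                   rate_inh=cfg.noise_rate,
                                   duration=cfg.duration + cfg.control_dt,
                                   dt=cfg.sim_step, reference=reference_current,
                                   target_snr=cfg.snr, seed=seed)
    return CSPlant(params, dt=cfg.control_dt, h=cfg.sim_step, noise=noise)


def _row(cfg, trial, arm, result, **extra) -> dict:
    row = {"trial": trial, "arm": arm, "config": cfg.digest(),
           "n_spikes": len(detect_spikes(result.voltage)),
           "max_abs_input": float(np.max(np.abs(result.current.values)))
           if len(result.current) else 0.0}
    row.update(result.metrics.as_dict())
    row.update(extra)
    return row


def _controlled_pair(cfg: ExperimentConfig, plant_type: str,
                     model: RBFNModel, ref: VoltageTrace,
                     i_ref: CurrentTrace, trial: int, rng) -> list[dict]:
    seed_mpc = int(rng.integers(2 ** 31))
    seed_ol = int(rng.integers(2 ** 31))
    plant = _fresh_plant(cfg, plant_type, i_ref, seed_mpc)
    res_mpc = run_mpc(plant, model, ref, cfg.mpc)
    plant = _fresh_plant(cfg, plant_type, i_ref, seed_ol)
    res_ol = open_loop_replay(plant, i_ref, ref)
    ref_spikes = len(detect_spikes(ref))
    return [
        _row(cfg, trial, "mpc", res_mpc, ref_spikes=ref_spikes,
             noise_seed=seed_mpc),
        _row(cfg, trial, "open_loop", res_ol, ref_spikes=ref_spikes,
             noise_seed=seed_ol),
    ]


def run_homogeneous(cfg: ExperimentConfig, models: dict[str, RBFNModel],
                    ) -> pd.DataFrame:
    """MPC vs open-loop replay of self-generated references."""
    model = models[cfg.plant_type]
    rng = np.random.default_rng(cfg.seed + 77)
    rows = []
    for trial in range(cfg.n_trials):
        ref, i_ref = make_reference(cfg, cfg.plant_type,
                                    seed=int(rng.integers(2 ** 31)))
        rows.extend(_controlled_pair(cfg, cfg.plant_type, model, ref,
                                     i_ref, trial, rng))
    return pd.DataFrame(rows)


def run_heterogeneous(cfg: ExperimentConfig, models: dict[str, RBFNModel],
                      ) -> pd.DataFrame:
    """Cross-type control, both directions.

    The reference is generated by one type; the other type's plant is
    driven either by MPC (with its own forecaster) or open-loop with the
    reference-generating current.
    """
    rng = np.random.default_rng(cfg.seed + 177)
    rows = []
    directions = [("type_i", "type_ii"), ("type_ii", "type_i")]
    for ref_type, plant_type in directions:
        model = models[plant_type]
        for trial in range(cfg.n_trials):
            ref, i_ref = make_reference(cfg, ref_type,
                                        seed=int(rng.integers(2 ** 31)))
            pair = _controlled_pair(cfg, plant_type, model, ref, i_ref,
                                    trial, rng)
            for row in pair:
                row["reference_type"] = ref_type
                row["plant_type"] = plant_type
            rows.extend(pair)
    return pd.DataFrame(rows)


def run_spike_train(cfg: ExperimentConfig, models: dict[str, RBFNModel],
                    spike_times, waveform_window: float = 10.0,
                    baseline: float = -65.0) -> pd.DataFrame:
    """Impose an arbitrary spike train with three controllers.

    The reference embeds the plant type's mean spike waveform (from a
    training-style recording) at the requested times.  Controllers: MPC,
    proportional feedback (gain ``cfg.kp``, clamped at the MPC bound),
    and open-loop rectangular pulses with a calibrated amplitude.  The
    plant runs without synaptic noise: the experiment probes whether each
    controller can place spikes at requested times, and the pulse
    calibration is defined on the noiseless neuron.
    """
    plant_type = cfg.plant_type
    model = models[plant_type]
    rng = np.random.default_rng(cfg.seed + 277)
    v_train, _ = _training_record(cfg, plant_type, seed=cfg.seed + 31)
    waveform = extract_mean_waveform(v_train, detect_spikes(v_train),
                                     window=waveform_window)
    ref_full = spikes_to_reference(spike_times, waveform, baseline=baseline,
                                   duration=cfg.duration, dt=cfg.control_dt)
    ref = VoltageTrace(values=ref_full.values[1:], dt=cfg.control_dt,
                       t0=cfg.control_dt)
    amplitude = calibrate_pulse_amplitude(neuron_params(plant_type),
                                          width=cfg.pulse_width,
                                          dt=cfg.control_dt, h=cfg.sim_step)
    rows = []
    n_req = len(spike_times)
    params = neuron_params(plant_type)
    for arm in ("mpc", "proportional", "pulse"):
        seed = int(rng.integers(2 ** 31))
        plant = CSPlant(params, dt=cfg.control_dt, h=cfg.sim_step)
        if arm == "mpc":
            res = run_mpc(plant, model, ref, cfg.mpc)
        elif arm == "proportional":
            res = proportional_control(plant, ref, kp=cfg.kp,
                                       clamp=cfg.mpc.i_max)
        else:
            res = pulse_control(plant, spike_times, width=cfg.pulse_width,
                                amplitude=amplitude, ref=ref)
        rows.append(_row(cfg, 0, arm, res, requested_spikes=n_req,
                         noise_seed=seed))
    return pd.DataFrame(rows)


def save_results(df: pd.DataFrame, cfg: ExperimentConfig, out_dir) -> None:
    """Write the metrics table and the locked config to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "metrics.csv", index=False)
    cfg.to_json(out / "config.lock.json")
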