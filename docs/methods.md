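# Methods

This note records the models, numerical choices, and known limitations of
`ddfmpc` — what the code assumes, which knobs matter, and what the tests
do and do not demonstrate.

## The plant: Connor–Stevens model

Membrane voltage obeys `C dV/dt = I_Na + I_K + I_A + I_l + I_noise +
I_inj` with `I_Na = g_Na m³h (E_Na − V)`, `I_K = g_K n⁴ (E_K − V)`,
`I_A = g_A a³b (E_A − V)`, `I_l = g_l (E_l − V)`.  Parameters (per 1 cm²
soma): C = 1 µF, g_Na = 120 mS, g_K = 20 mS, g_l = 0.3 mS.  Gating
kinetics are the classic Connor–Stevens rate functions in the **original
voltage convention**: E_Na = 50 mV, E_K = −77 mV, E_A = −80 mV, with the
HH-type α/β rates voltage-shifted accordingly and temperature-scaled by
3.8 (3.8/2 for the n gate), and the empirically fitted A-current
steady-state/time-constant curves.  Many textbooks present the same
model shifted +5 mV (E_Na = 55, E_K = −72, E_A = −75, E_l = −17); the
two are related by an exact change of variables.  The original
convention is used here because the two leak reversals that define the
excitability types — **Type-I**: g_A = 47.7 mS, E_l = −22 mV;
**Type-II**: g_A = 0, E_l = −72.8 mV — are stated in it, and only in it
do the two types share a resting potential (≈ −72.9 mV), which is the
point of retuning E_l when the A-current is removed.  In this
convention the Type-I model fires repetitively at a 9 µA step and the
Type-II model shows its discontinuous rate jump, the behaviors the test
suite asserts.

### Integration

Fixed-step, deterministic, h = 0.02 ms.  Gating variables use the
exponential (Rush–Larsen) update `x ← x_∞ + (x − x_∞)·exp(−h/τ_x)`
evaluated at the current voltage — exact for frozen V, unconditionally
stable, and it confines every gate to [0, 1] structurally.  The voltage
then takes an RK4 step with gates held fixed.  Plain RK4 on the full
system was rejected: when a Type-II plant (leak-only rest) is driven by
Type-I-scale negative currents, V falls below −130 mV, β_m·h ≫ 1, and
explicit integration of the gate equations is unstable there.  Input
currents are zero-order-held between their samples.  Initial conditions
come from relaxing the model 500 ms at zero input.

### Stimuli and noise

Chaotic currents: the Lorenz-63 system (σ = 10, ρ = 28, β = 8/3 — the
canonical chaotic set, since only "Lorenz-63" constrains them) scaled in
time by τ = 20 with t in ms, output `A·x(t)`; A = 1.8 µA (Type-I) and
0.5 µA (Type-II) per unit x.  1000 native time units of burn-in put the
trajectory on the attractor before sampling; different trials use
different post-burn-in initial conditions.  The origin is left exact so
`x₀ = y₀ = z₀ = 0` yields the zero current.

Noise: independent excitatory and inhibitory Poisson trains, 20 Hz
each, convolved with the peak-normalized alpha kernel
`(t/τ_s)·exp(1 − t/τ_s)`, τ_s = 10 ms (truncated at 10 τ_s); the
inhibitory train is negated.  The sum is rescaled so that
std(I_inj)/std(I_noise) equals the target SNR (default 5).  SNR is
defined as a ratio of standard deviations — the most common convention;
the scaling makes the realized ratio exact by construction.  All noise
is seeded and bitwise reproducible.

### Spike detection and f–I curves

Spikes are upward crossings of 30 mV (one event per crossing; no
refractory window is needed because crossings are separated by
repolarization).  f–I curves report the **steady-state** rate: spikes in
the first 100 ms of each 300 ms step are discarded.  Without the
discard, a single transient spike at step onset — typical just below the
Type-II threshold, where the rest state is still stable — would register
as a tiny "sustained" rate and invert the onset-topology comparison
between the types.

## The forecaster

Delay embedding `S_n = (V_n, V_{n−τ*}, …)` with τ* = 1 sample at 10 kHz;
the dimension is selected by simplex projection (nearest-neighbor
one-step forecasting with D_e + 1 neighbors, exponential distance
weights `exp(−d/d₁)`, 75/25 library/prediction split, skill = Pearson
correlation; ties go to the smaller dimension).  On 5 s of noisy CS
voltage this selects D_e = 2 for both types (majority over noise seeds).

The one-step model `V_{n+1} = V_n + F_RBF(S_n) + α(I_{n+1} + I_n)` is
linear in its trainable parameters, so training is a single ridge
regression.  Defaults: N = 50 k-means centers
(scikit-learn k-means++, seeded), R = 0.01 mV⁻², λ from a logarithmic
grid 10⁻⁸…10², 11 points, by 10-fold cross-validation on **contiguous**
blocks (time-series data; shuffled folds would leak temporally adjacent
samples), ties toward the larger λ.  The ridge solution is computed as
an augmented least-squares problem `[X; √λ I] W = [Y; 0]` for numerical
conditioning; tests verify it against the explicit normal-equations
closed form.  Open-loop rollouts carry a divergence guard at
|V| > 500 mV (flagged, trajectory held).

### Known limitation: free-running Type-I forecasts

One-step accuracy is high for both types (increment R² > 0.99).  In
*free-running* mode (predictions fed back for thousands of steps) the
Type-II forecaster stays accurate (voltage R² ≈ 0.7 over 5 s, spike
counts within a few percent), but the Type-I forecaster **over-fires**
during epochs of moderate depolarizing drive: the A-current's
inactivation state b varies on multi-millisecond timescales and is not
reconstructible from a 0.2 ms voltage window, so the learned map
averages over hidden-state values and loses the A-current's
spike-delaying effect.  Its long-horizon spike-distance to the noiseless
plant (~0.20 on a 1 s novel stimulus) exceeds the spike-distance spread
induced by SNR-5 noise (~0.12 median), so the forecast-versus-noise
parity check passes for Type-II but not Type-I.  Closed-loop control is
unaffected — the controller re-seeds the model with the measured voltage
every 0.1 ms, so model error never accumulates beyond the 0.5 ms
horizon — which is why MPC tracks Type-I references essentially
perfectly even though the same model cannot forecast them open-loop.

## The controllers

**MPC.**  Horizon T = 5 control periods of Δt = 0.1 ms; cost weights
s = q = 1, r = 0.01; symmetric input bounds ±100 µA.  The weights are
package defaults (exposed in `MPCConfig`): r must be positive to
suppress input chatter but small enough not to fight tracking; 0.01
balances the two at these units (1 mV error ≈ 10 µA of corrective
drive).  The bound is symmetric: only an upper bound is stated for the
main loop, but the proportional baseline is described as clamped at
±100 µA, and an unbounded negative rail is physically meaningless.  The
horizon problem is solved by L-BFGS-B with box bounds and an exact
analytic gradient obtained by forward sensitivity analysis through the
RBFN rollout; each solve warm-starts from the previous solution shifted
one step.  The hold-previous-input plan is always evaluated as a
candidate, so the applied plan provably never costs more than holding
(and solver failures degrade to that fallback rather than raising
mid-loop).  Horizon errors and ΔI are indexed relative to the current
measurement, and the embedding history is refreshed from plant
measurements, never from model predictions.

**Baselines.**  Proportional: `I = clip(K_p (V − V^ref), ±100 µA)`,
K_p = −2, executed at the control period.  Open-loop replay applies a
stored current with no feedback.  Pulse control applies 2 ms rectangular
pulses at requested spike times; the amplitude is calibrated per neuron
type by sweeping on the noiseless plant for the smallest amplitude that
elicits exactly one spike per pulse (and does so at the next grid point
too, to avoid a knife-edge choice).

## Metrics

MSE in mV² over the full trial.  ISI-distance: time average of
`|x₁ − x₂|/max(x₁, x₂)` over the instantaneous interspike intervals.
SPIKE-distance: time average of the weighted nearest-spike dissimilarity
profile (see `ddfmpc.metrics` for the exact expression).  Both use
auxiliary spikes at the window edges (the standard edge correction; the
identity-gives-zero property is exact either way), are computed by exact
piecewise integration between merged spike events, and return 1 when one
train is empty and the other is not (an empty train carries no timing
information; the sentinel keeps degenerate trials well-defined).  Tests check
both distances against an independent pointwise-profile oracle.

## Experiments and problem sizes

Reference trajectories are generated by simulating the plant under a
fresh chaotic current — held at the control rate, exactly as a
controller would apply it, so noiseless open-loop replay reproduces the
reference bitwise — plus a fresh noise draw; the controlled plant gets
its own independent noise draw (the trial-to-trial-variability premise).
Heterogeneous runs swap the reference-generating type and the plant
type in both directions.  Spike-train control builds its reference by
pasting the plant type's mean spike waveform (±10 ms, aligned on the
detection sample, so threshold detection recovers the requested times to
within one sample) into a −65 mV baseline, and runs on the noiseless
plant, where "one spike per requested time" is well-defined for all
three controllers.

The default experiment scale is 10 trials × 500 ms per condition with
5 s of training data — large enough for stable medians of the three
metrics on a single CPU; the full-scale study (50 × 1 s) is a config
change (`n_trials`, `duration`).  Forecast-parity checks use a 1 s
novel-stimulus window.  Every run records seeds and a config digest, and
rerunning a config reproduces its metrics table bitwise.

## What the synthetic data does not capture

The plant is a point neuron with deterministic channels and additive,
stationary synaptic noise; there is no measurement noise, electrode
filtering, access resistance, temperature drift, or channel
stochasticity, and the 1 cm² soma normalization makes the µA input scale
larger than typical patch-clamp currents.  Passing tests therefore show
that the forecaster-plus-MPC loop recovers control under hidden
nonlinear dynamics and process noise — not that the specific
hyperparameters transfer to biological recordings.
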