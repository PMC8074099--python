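# Methods

## Model structure and assumptions

The simulator is a population firing-rate (Wilson–Cowan-type) model of the
dorsal-horn gate-control circuit. Three homogeneous populations — projection
(P), excitatory (E) and inhibitory (I) — evolve

    τ_X dr_X/dt = −r_X + f_X(u_X),

where f_X(u) = M_X / (1 + exp(−γ_X (u − θ_X))) is a logistic response curve
(maximal rate M_X, half-activation drive θ_X, gain γ_X) and the drives are

    u_P = w_AβP·Ab(t) + g(r_P)·w_CP·C(t) + w_EP·r_E − w_IP·r_I
    u_E = w_AβE·Ab(t) + w_CE·C(t)
    u_I = w_AβI·Ab(t).

Assumptions worth making explicit:

* **Homogeneous populations.** Real DH neurons are heterogeneous; each
  population here is a single rate variable with one response curve.
* **Gate-control wiring.** I is the only inhibitory projection, it targets P,
  and it is driven by the touch (Aβ) fibers. This is what makes a well-timed
  Aβ volley analgesic.
* **Instantaneous NMDA modulation.** The C→P weight is multiplied by a Hill
  function of the current projection rate,
  g(r) = base + (sat − base)·r²/(r² + h²), bounded in [base, sat] with
  g(0) = base. This is a memoryless stand-in for NMDA-dependent synaptic
  facilitation: it reproduces wind-up (closely spaced C pulses ride on
  residual P activity and are amplified) without adding a state variable.
* **Rate-coded afferents.** Fibers are Poisson; the network sees only the
  bundle-averaged rate. Spike-level correlations between fibers are absent
  by construction.

## Afferent input

Each fiber fires as an inhomogeneous Poisson process: 1 Hz background
everywhere plus a stimulus pulse of 150 Hz for 20 ms at onset 500 ms.
Sampling is exact per constant-rate piece (Poisson count + uniform times).
Conduction delays are drawn once per fiber and realization, uniform on
[0, 20] ms (Aβ, 380 fibers) and [90, 300] ms (C, 820 fibers): a delay is an
axon property, not a per-spike property. The uniform family is the simplest
distribution consistent with the stated arrival ranges. Because the C delay
spread (210 ms) is much wider than the pulse (20 ms), the C drive is a broad
plateau of ≈ 1 + 150·20/210 ≈ 15 Hz over ≈ [610, 800] ms, while the Aβ drive
is a sharp triangular volley peaking at ≈ 151 Hz at 520 ms.

The stimulus amplitude is a calibration-bound value (see below): it has no
independent experimental anchor and only the product of amplitude and
afferent weights matters to the network.

Bundle rates are computed by binning all spikes in 1 ms bins
(rate = count/(n_fibers·dt); total spike mass is conserved exactly before
smoothing) and smoothing with a Gaussian kernel of 5 ms standard deviation —
wide enough to give the ODEs a smooth drive, narrow enough not to hide
injury-induced oscillations. Spikes pushed past the simulation end by large
delays are dropped with a logged warning.

## Injury rules

Transforms act on a fiber's whole (undelayed) spike train:

* **evoked** — each input spike independently triggers, with probability p,
  k extra spikes at +2, +4, … ms (fixed 2 ms burst spacing; placement is not
  otherwise constrained, and a short burst is the natural reading of an
  "evoked" volley). Evoked spikes do not themselves trigger bursts.
  Expected count multiplier 1 + p·k.
* **block** — square-wave conduction gate of period 2π/ω ms, 50% duty,
  passing at t = phase_offset (default 0). ω is an angular frequency in
  rad/ms. The 50% duty cycle is the symmetric choice; it removes half of a
  long stationary train.
* **refractory** — left-to-right dead-time scan: a spike is deleted when its
  interval to the most recent *surviving* spike is < τ. This matches the
  physiological meaning of an enlarged refractory period and admits the
  closed-form surviving rate r/(1 + rτ) used as an analytic test.
* **delay** — shift all spikes by +d ms.
* **none / total_block** — the trivial limits.

Injuries are assigned to a uniformly random subset of
round-half-away-from-zero(fraction · n_fibers) fibers.

## Default parameters and the calibration procedure

The circuit structure above is fixed; the default numerical values
(`src/dorsalhorn/data/default_params.yaml`) were produced by calibrating the
free parameters against the model's documented behaviours, in this order:

1. **Resting state** ≈ 1 Hz projection rate with 1 Hz background on both
   bundles (sets θ_P·γ_P against the tonic inhibition w_IP·f_I(w_AβI)).
2. **Healthy response**: the C-window response crosses the 25 Hz pain
   threshold with margin (plateau ≈ 37 Hz deterministically, peaks ≈ 40–47 Hz
   with Poisson noise), while Aβ input alone never crosses it (the touch
   volley yields a small sub-threshold deflection: w_AβP is weak and the
   recruited inhibition cancels most of the direct excitation).
3. **Blocking cliff**: under intermittent blocking (ω = 10 rad/ms) the
   plateau falls through 25 Hz at an injured fraction near 25%, so the
   threshold-crossing count N_C peaks at an interior fraction.
4. **Delay optimum**: with half the Aβ fibers delayed, mean A_total is
   minimized at d = 125 ms.

Constraints 3 and 4 pull against each other and are resolved by the NMDA
wind-up kinetics: the C response *climbs slowly* (≈ 610–660 ms) because the
pre-wind-up fixed point sits just above the NMDA half-rate (13.5 Hz), so the
positive feedback bootstraps with an effective time constant several times
τ_P. A delayed Aβ volley is maximally destructive when its inhibition
catches r_P inside this fragile climb (volley [625, 665] ms for d = 125);
earlier it suppresses a response that is still near baseline, later it only
dents the g-saturated plateau. The slow-E pathway (τ_E = 30 ms) and the
fast inhibitory interneurons (τ_I = 6 ms) set the climb and the volley
timing respectively. The optimum's location was verified to be stable across
independent master seeds before the defaults were frozen.

Key defaults (full set in the YAML file):

| parameter | value | meaning |
|---|---|---|
| τ_P, τ_E, τ_I | 10, 30, 6 ms | population time constants |
| w_AβP, w_AβI, w_AβE | 0.05, 0.6, 0 | touch pathways |
| w_CP, w_CE, w_EP, w_IP | 1.7, 1.0, 0.6, 0.3 | pain and interneuron pathways |
| M_P, θ_P, γ_P | 60 Hz, 54, 0.0755 | projection response curve |
| NMDA base, sat, h, hill | 0.6, 2.1, 13.5 Hz, 2 | C→P weight modulation |
| stimulus | 150 Hz × 20 ms at 500 ms | per-fiber pulse |
| π_thresh | 25 Hz | painful firing-rate threshold |
| marker window | [600, 800] ms | C-arrival response window |

w_AβE = 0 is a deliberate wiring choice: a direct Aβ→E→P route would fight
the gate-control inhibition that the delayed-volley experiment depends on;
E is driven by the C fibers.

## Markers and windows

Markers are computed on [t₀, t_f] = [600, 800] ms (configurable): wide
enough to contain the whole C response under every injury protocol,
including delays that spread it. A_total and A\* use the trapezoidal rule on
the trace grid with linearly interpolated endpoints. A crossing is a strict
sign change of (trace − threshold) between consecutive samples; samples
exactly at threshold inherit the previous sign, so grid coincidences cannot
manufacture crossings. Because the C drive outlasts the window by ≈ 20 ms,
a healthy response is typically still above threshold at t_f and N_C is
odd (1); that asymmetry is irrelevant to the interior N_C peak under
blocking, which is driven by the response hovering at the threshold.
An automatic window mode (longest supra-baseline run within a search range)
is provided alongside the fixed default; the fixed window is used for all
shipped protocols. In fraction sweeps the total-area marker is also the
quantity called A₀ in some marker lists; it is treated as identical to
A_total here.

## Numerics

* **Integrator**: explicit Euler, dt = 0.1 ms (input traces at 1 ms are
  linearly interpolated to the fine grid). E and I have purely feedforward
  drive, so their Euler recursions are evaluated as linear filters over the
  whole trace; P is stepped in a scalar loop because g(r_P) feeds back. A
  step-halving test keeps every sample within 1% under dt → dt/2.
  Non-finite states raise an integration error naming the step; steps too
  large for the time constants are rejected up front.
* **Initial condition**: the zero-input fixed point (closed-form, since the
  NMDA term vanishes with C = 0), followed by a 200 ms burn-in with inputs
  frozen at their first sample.
* **Randomness**: a single master seed per experiment; realization i uses
  the i-th spawned child, and per-fiber streams are derived from the fiber
  index, so any fiber's train is reproducible regardless of how many fibers
  or sweep points are evaluated. Sweeps use common random numbers (same
  base trains per realization index across all grid points, injuries applied
  on top), which sharpens optima and contours by pairing.
* **Sweep defaults**: delay grid 50–300 ms in 25 ms steps; fraction grid
  0–100% in 5% steps; 30 realizations per point; mixed grid 5 × 5 with 10
  realizations per cell. These resolve the delay optimum and the interior
  N_C peak at desk scale.

## What the generator does and does not emulate

The synthetic afferents reproduce the statistics the model is sensitive to:
Poisson counts at the configured rates, the arrival-time dispersion of the
two fiber classes, and injury-induced distortions at the single-fiber level.
They do not include inter-fiber correlation, adaptation or bursting of real
nociceptors, ectopic (stimulus-independent) activity of injured fibers, or
any top-down modulation. Passing tests therefore validate the circuit-level
mechanisms (gating, wind-up, the injury-to-marker mappings), not a
quantitative match to any physiological recording.

## Known limitations

* One injury rule per fiber population per run; real lesions mix regimes.
* The NMDA multiplier is memoryless; slow facilitation dynamics would change
  the quantitative (not qualitative) wind-up and delay-optimum behaviour.
* All parameter values are calibration products constrained by the target
  behaviours above, not independently measured quantities; conclusions
  should rest on the qualitative structure (directions of marker changes,
  existence and approximate location of the optimum/peak), which is what the
  test suite asserts.
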