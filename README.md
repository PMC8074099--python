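# dorsalhorn

A firing-rate simulator of pain processing in the spinal dorsal horn, built to
study how axonal injury to the afferent fibers reshapes the pain response at
the network level.

## The scientific problem

The dorsal horn (DH) integrates incoming sensory signals before they are
relayed to the brain. In the classic gate-control circuit, projection neurons
(P) — whose firing rate is the pain readout — receive input from excitatory
(E) and inhibitory (I) interneurons and directly from two afferent fiber
classes: fast, myelinated Aβ fibers carrying touch, and slow, unmyelinated C
fibers carrying pain. Touch input recruits the inhibitory interneurons and
can thereby *gate* (suppress) the pain signal.

Axonal damage — focal axonal swellings, demyelination — does not simply
silence a fiber; it distorts the spike trains it conducts. This package
implements four phenomenological distortions on per-fiber spike trains and
asks what each does to the population-level pain response:

* **evoked potentials** — an input spike triggers k extra spikes with
  probability p (spike gain);
* **intermittent blocking** — conduction alternates between total block and
  faithful transmission with period 2π/ω (50% duty);
* **increased refractoriness** — a spike is deleted if it follows the previous
  surviving spike within τ ms (dead-time thinning, which attenuates
  high-rate trains disproportionately: the surviving rate of a Poisson train
  of rate r is r/(1 + rτ));
* **delay** — the whole train is shifted later by d ms.

## The model

Each of 380 Aβ and 820 C fibers fires as an inhomogeneous Poisson process
(1 Hz background, a brief high-rate pulse at t = 500 ms encoding a painful
stimulus) and arrives with a fiber-specific conduction delay (uniform 0–20 ms
for Aβ, 90–300 ms for C). Bundle-averaged firing rates Ab(t), C(t) drive
Wilson–Cowan-type dynamics

    τ_X dr_X/dt = −r_X + f_X(u_X),   X ∈ {P, E, I}

    u_P = w_AβP·Ab + g(r_P)·w_CP·C + w_EP·r_E − w_IP·r_I
    u_E = w_AβE·Ab + w_CE·C
    u_I = w_AβI·Ab

with logistic response curves f_X and a bounded, monotonically increasing
NMDA factor g(r_P) on the C→P weight that produces wind-up. The pain
response is summarised over the C-arrival window [600, 800] ms by five
markers relative to the calibrated painful threshold π_thresh = 25 Hz:
A_total (area under r_P), A\* (area above threshold), π\* = A\*/|t_f − t_0|,
π_max (peak rate) and N_C (threshold crossings).

## Worked example

A single healthy realization (also available from Python via
`dorsalhorn.run_realization`):

```
$ dorsalhorn simulate --seed 1 --outdir demo
{
  "a_total": 5456.1711450050325,
  "a_star": 1666.9833835943027,
  "pi_star": 8.334916917971514,
  "pi_max": 46.629742611816525,
  "n_crossings": 1,
  "window_t0": 600.0,
  "window_tf": 800.0,
  "threshold": 25.0
}
```

The projection output rides at ~1 Hz at rest, shows a small sub-threshold
deflection when the Aβ volley reaches the DH (~500–540 ms) and then a
sustained painful response (peak ≈ 47 Hz, well above the 25 Hz threshold)
while the dispersed C volley arrives (~600–800 ms). `a_total` is the total
response area in Hz·ms over the window; `a_star` the area above threshold;
`n_crossings` counts 25 Hz crossings (the response is still above threshold
at the window edge here, hence the odd count). Traces for the five signals
(Ab drive, C drive, r_P, r_E, r_I) are written as CSV next to the markers.

Sweeping the injury delay applied to half of the Aβ fibers:

```
$ dorsalhorn sweep --mode delay --seed 1 --realizations 10 --outdir demo_sweep \
      --grid 75,100,125,150,175
optimal delay: 125 ms
```

A 125 ms delay re-times the touch volley so that it recruits the inhibitory
interneurons just as the C response begins to wind up — maximal pain
inhibition by the gate-control mechanism. The other protocols are
`dorsalhorn sweep --mode fraction` (markers versus injured C fraction for any
rule) and `dorsalhorn grid` (the mixed "tug-of-war": evoked potentials on C
fibers against delays on Aβ fibers, with the zero-change contour).

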