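# Methods

## Model

Each network node is a lumped neural population coupled to an astrocyte
compartment. The state per node is `(Ex, In, Glu, h)`: excitatory activity,
inhibitory activity, astrocytic glutamate concentration, and a glutamate
recovery variable. With the sigmoid rate function
`f(x) = 1 / (1 + eps^(-x))` (`eps = 1000`, so `f` is close to a step), the
node dynamics are

```
dEx/dt  = tau_ex * ( h_ex - Ex + C1 f(Ex) - C2 f(In)
                     + c_net * sum_j a_ij f(Ex_j) + Cu f(I_astro) ) + S(t)
dIn/dt  = tau_in * ( h_in - In + C3 Ex )
mu  dGlu/dt = -Glu + Z - kappa * h
eta dh/dt   = -h + Glu
```

with the astrocyte pieces

```
Ca      = k_ca * f(Ex)            (calcium tracks the firing rate linearly)
Z       = max(0, Ca - ca_th)      (suprathreshold calcium drives release)
I_astro = 10 * lambda_a * Glu     (glutamate feeds back onto Ex)
```

`a_ij` is the binary symmetric adjacency matrix of a Watts–Strogatz graph
(defaults `N = 50`, ring degree `N0 = 2`, rewiring probability `p = 0.5`),
and `S(t)` is an optional stimulation term added to targeted nodes. The
model is dimensionless; time labels are nominal milliseconds. Integration
is forward Euler at `dt = 0.05` over `t_total = 100` (2000 steps); a
classical RK4 stepper is available and is used in the convergence tests.

The neuronal constants are `C1 = 1`, `C2 = 15`, `C3 = 6.1`, `Cu = 6`,
`tau_ex = 1.97`, `tau_in = 3.0`, `h_ex = -0.5`, `h_in = -1.4`.

### Discharge modes

Four qualitative regimes are selected by a single-parameter override:

| mode | override          | regime |
|------|-------------------|--------|
| 1    | `tau_in = 0.001`  | quiescent: inhibition is frozen at its initial level and the population settles |
| 2    | `h_ex = -0.6`     | large-amplitude, high-frequency seizure oscillation |
| 3    | `tau_ex = 0.6`    | smaller, slower oscillation (the slowed excitatory time scale damps the relaxation swing) |
| 4    | `kappa = 1`       | saturated discharge: glutamate rises and stabilizes at an elevated plateau |

A mechanistic note on mode 1: a population whose inhibition is frozen near
`f(In) = 0.5` is pulled far below threshold and releases no glutamate. Its
glutamate then relaxes to zero and, because the recovery pool `h` stays
positive, is held slightly negative ("pinned") for a time of order
`eta / (1 + kappa) * log(10 lambda_a kappa h)`; while pinned, the astrocyte
gate `f(I_astro)` is off and the population has a stable quiescent fixed
point. The shipped constants make that pin outlast the run. The pin relies
on the recovery pool starting non-negative, which is why the random initial
condition draws `Glu` and `h` from `[0, 0.1]` (concentrations) while `Ex`
and `In` are drawn from `[-0.1, 0.1]`. A mode-1 population whose initial
`In` lands below about `-0.05` starts with weakened (not half-on)
inhibition and can ignite; quiescence is therefore a property of typical,
not all, initial conditions, and the tests assert it accordingly.

## Calibrated constants

The astrocyte and coupling constants are not part of the printed parameter
set and were fixed by a documented two-stage calibration, after which they
were not revisited:

1. Grid/random search for the region reproducing the qualitative
   signatures: the four single-population discharge modes above; a
   synchronized baseline network (mean pairwise PLV > 0.85 on the
   mode-2/3/1 composition); pre-surgical summed glutamate that rises and
   then plateaus (final-quarter mean above 0.8 of the peak); and
   near-zero residual glutamate after removing all seizing nodes.
2. The glutamate scale was then anchored so the pre-surgical summed
   glutamate peaks near 300 on the 50-node network. The dynamics are
   exactly invariant under `k_ca, ca_th -> c*k_ca, c*ca_th` with
   `lambda_a -> lambda_a / c`, so this step rescales glutamate without
   touching the neuronal trajectories.

Shipped defaults (`data/default_config.yaml`):

| constant  | value | role |
|-----------|-------|------|
| `k_ca`    | 15    | firing-rate-to-calcium slope |
| `ca_th`   | 9     | calcium threshold (0.6 of the slope) |
| `kappa`   | 0.5   | glutamate–recovery coupling; mode 4 sets 1 |
| `mu_glu`  | 1     | glutamate time constant (fast release/decay) |
| `eta_h`   | 800   | recovery time constant (slow pool, sustains the mode-1 pin and the glutamate plateau) |
| `lambda_a`| 165   | feedback strength; with the sharp sigmoid it acts as a gate: astrocyte drive is fully on for `Glu` above ~2e-4 and off for `Glu` pinned negative |
| `c_net`   | 6     | network coupling coefficient |

`c_net = 6` sits just above the locking transition of the mixed mode-2/3
population (their natural frequencies differ by ~14%); weaker coupling
leaves the sparse degree-2 graph unsynchronized, stronger coupling makes
the lock rigid. At the chosen value the synchronized state is marginally
stable: it holds unperturbed (baseline PLV ~0.93) but perturbing the
high-degree nodes desynchronizes them gradually with the number of
stimulated nodes. This marginal regime is what makes small-amplitude
stimulation effective at all — in a rigidly locked regime stimuli of
amplitude up to 0.3 (against derivative scales of order 30) leave the PLV
unchanged.

## Stimulation

Three waveforms target the top-`n` degree-ranked nodes (an alternative
selector ranks nodes by baseline PLV row sums): per-step uniform noise on
`[-z, z]` (zero mean), a sinusoid `z sin(2 pi t / period)`, and a unipolar
square wave (0 or `+z`, duty 0.5). Period defaults to 10 time units (10
cycles per run) and is configurable; the waveform frequency, noise
distribution and duty cycle are package choices, not printed values. One
shared waveform drives all targets; the random waveform is drawn once per
integration step and held across RK4 stages.

## Synchronization metrics

Phases come from the Hilbert analytic signal of each node's mean-removed
`Ex` trace after dropping the first 10% of samples (initial-condition decay
would deflate locking). Pairwise PLV is the modulus of the time-averaged
unit phasor of the phase difference (the modulus makes it a real number in
[0, 1]); the network PLV averages the active upper triangle. The Kuramoto
order parameter `R(t)` is the per-sample modulus of the across-node mean
phasor, and the coefficient of variation (population standard deviation
over mean) of `R(t)` quantifies how unsteady the synchrony is. CV of the
across-node mean `Ex` signal is available behind `cv_source="mean_ex"`, but
that series has near-zero, sign-indefinite mean, which makes its CV
ill-conditioned; the order-parameter source is the default. Resected nodes
are excluded from phases, PLV, `R(t)` and glutamate sums; their rows stay
in the arrays (as NaN in the PLV matrix) so indices are stable across
plans.

The headline glutamate series is the across-active-node sum; its maximum
and the mean over the final quarter of samples are the peak and plateau.

## Experiments and problem sizes

- Mode gallery: one uncoupled population per mode, full run length.
  Classifier thresholds: quiescent = final-quarter `Ex` range and mean
  `|Glu|` below 0.5; oscillatory = at least 3 sign changes of the
  mean-removed `Ex`; saturated = final-quarter glutamate standard deviation
  below the first-quarter value with the plateau above 0.5. The flags are
  descriptive and not mutually exclusive (a seizing population also carries
  sustained glutamate).
- Stimulation sweeps: node-count grid 0–30 (intensity fixed at 0.1) and
  intensity grid 0.01–0.3 in 30 steps (20 targets), 10 replicate seeds per
  point, fresh Watts–Strogatz graph and initial condition per replicate.
  Each run is 50 nodes x 2000 Euler steps (~0.2 s); a full sweep with
  replicates completes in a few minutes.
- Resection: surgery-scheme allocation (20/8/2/20 nodes in modes 2/3/4/1 in
  degree-rank order), plans removing modes {2}, {3}, {4} or {2,3,4}, plan 0
  the unresected baseline; 10 replicates. At `N = 100` allocations scale
  proportionally (largest-remainder rounding: 40/16/4/40).

## What the simulations do and do not show

All experiments are self-generated: the Watts–Strogatz substrate and random
initial conditions stand in for real cortical connectivity and ongoing
activity. The model reproduces the qualitative treatment phenomenology —
synchronized seizure-like baseline, graded desynchronization by stimulating
high-degree nodes with random noise the least effective waveform, glutamate
load falling most when the high-degree seizing nodes are resected and
collapsing when all seizing modes are removed. Two quantitative families
are not reproducible in this model class and are left failing in the
acceptance checks with analysis: (a) stimulated-network PLV plateaus near
0.85–0.9 for the weaker waveforms (the marginally stable lock, required for
any stimulation response, de-correlates the stimulated hubs more deeply
than that), and (b) a summed-glutamate peak collapse from ~300 to ~110 upon
removing only the two mode-4 nodes (the `kappa` override differentiates
glutamate only after the slow recovery pool equilibrates, which post-dates
the network peak; the required per-node dominance is unreachable for any
constant assignment we searched).

## Numerical choices and degenerate inputs

- Forward Euler at the stated step is the default; RK4 is provided for
  convergence checking (the suite verifies the Euler–RK4 gap shrinks as
  `dt` decreases).
- Non-finite states abort the run with the step index and time.
- Glutamate is integrated as written and may transiently cross zero (the
  pin above depends on it); it is not clamped.
- A constant signal has no phase and raises a degenerate-signal error; a
  zero-mean series has no CV and raises an undefined-CV error.
- Degree ties in rankings break by ascending node index, making rankings,
  mode allocations and stimulus targets reproducible.
- Per-run seeds for replicated experiments are spawned from the experiment
  seed via `numpy` `SeedSequence`, keeping every run below `2**31` and
  bit-for-bit reproducible from the manifest.

## Known limitations

- The marginally stable synchronized state means stimulated-run PLV has a
  cliff-like component: even tiny stimuli de-correlate the stimulated hubs
  over the run; intensity then modulates the effect only weakly. The
  waveform ordering (noise weakest) is reproduced; the printed intermediate
  plateau levels are not.
- Mode-4 populations differ from mode-2 only through the glutamate pool,
  not through their discharge trace; "saturation" is expressed in the
  astrocytic variable.
- CV-based plan rankings are noisy across network realizations; only the
  direction "resection lowers CV relative to the untreated network" is
  robust here.
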