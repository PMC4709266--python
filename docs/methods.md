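# Methods

## The model

Each inner hair cell (IHC) is a single electrical compartment,

```
C_m dV/dt = I_inj(t) − Σ_x I_x(V, q_x) − I_leak(V) − I_MT(V, x)
```

with `C_m` = 12.4 pF (apical) / 11.7 pF (basal). Every voltage-gated K⁺
conductance `x` carries

```
I_x   = g_x · q_x · (V − E_K),          E_K = −82 mV
dq_x/dt = (q_∞(V) − q_x)/τ(V)
q_∞(V) = [1 + exp((V_half − V)/S)]^(−power)
τ(V)   = τ_base + τ_amp · exp(−((V − τ_Vhalf)/τ_σ)²)
```

First-order Hodgkin–Huxley-style activation with a Boltzmann steady state
and a bell-shaped voltage-dependent time constant; there is no inactivation
and no explicit intracellular Ca²⁺ state (the Ca²⁺ dependence of the
BK-type current is folded into its voltage dependence — justified by the
observation that endogenous Ca²⁺ buffering does not alter these currents).
`power` is 1 for all shipped conductances.

Four gated conductances per cell:

| name      | role | V_half (mV) | S (mV) | τ range (ms) |
|-----------|------|------------|--------|--------------|
| `K_f`     | fast BK-type current; settles before the 2 ms peak-current measurement | −45 (apical), −22 (basal) | 7 | 0.15–0.4 |
| `K_n_neg` | negatively activating KCNQ-type current, substantially open at rest | −85 | 9 | 3–20 |
| `K_n_pos` | more positively activating linopirdine-sensitive delayed rectifier; large only in apical cells | −42 | 9 | 1.5–7.5 |
| `K_s`     | slow delayed rectifier; the main basal outward current at depolarized potentials | −5 | 12 | 8–23 |

plus an ohmic leak (conductance and reversal set by calibration; the apical
leak calibrates to a depolarized reversal, a lumped nonselective cation
leak that carries the standing inward current balancing the K_n
conductances at rest in 1.3 mM Ca²⁺).

The apical/basal difference in `K_f` half-activation stands in for the
tonotopic difference in BK Ca²⁺-microdomain coupling. It matters for one
qualitative behaviour: with the apical BK at −45 mV, blocking the
linopirdine-sensitive currents leaves the apical cell sitting near −37 mV
under the 500 pA holding protocol with a low, basal-like conductance — the
"linopirdine makes apical cells basal-like" phenotype. No printed numeric
target depends on this choice.

**Mechanotransducer (MT) current.** `I_MT = g_MT · Po(x) · (V − E_MT)` with
`E_MT = 0 mV` and a two-state Boltzmann of dimensionless bundle displacement
`Po(x) = [1 + exp((x₀_c − x)/s_x)]^(−1)`. The set point `x₀_c` is shifted
per extracellular condition so that `Po(0)` equals that condition's resting
open probability: endolymph-like 40 µM Ca²⁺ raises it (calibrated ≈ 0.42
apical, ≈ 0.07 basal), 1.3 mM Ca²⁺ calibrates to ≈ 0, and
dihydrostreptomycin (DHS) zeroes the MT conductance entirely. This is the
only effect of the Ca²⁺ condition in the model — no change to
single-channel conductance or to the basolateral currents — which is the
interpretation supported by the DHS-returns-to-control observation.
`g_MT` (13 / 12 nS) puts the saturating MT current at −84 mV near 1.1 /
1.0 nA. Fluid-jet driver voltage maps linearly to displacement
(±20 V → ±6 units, deep into both saturations).

**Conditions** compose a Ca²⁺ level with blockers: linopirdine (80 µM)
zeroes `K_n_neg` and `K_n_pos`, iberiotoxin (60 nM) zeroes `K_f`, DHS
(100 µM) zeroes the MT conductance. Multipliers are all-or-none; partial
block is supported by the `Condition.effects` mapping but not used by any
shipped condition.

## Calibration

Free parameters per preset: one scale factor per gated conductance, the
leak conductance and reversal, and the two MT resting open probabilities.
Five residuals: zero net current at the measured resting potential in each
Ca²⁺ condition; the resting MT current magnitude (`g_MT · Po_rest · 84 mV`,
referenced to the −84 mV holding potential of the MT-current recordings);
the steady-state slope conductance at the cell's operating point, computed
exactly as the analysis pipeline computes it (least-squares line through
the steady-state I-V points of the standard −144 → +36 mV step family
within ±10 mV); and the requirement that MT block in low Ca²⁺ returns the
resting potential to its 1.3 mM value. A weak log-scale regularization
keeps the under-determined scale factors near the designed base values so
the pharmacology structure (which conductance dominates which cell) is
preserved. Bounded least squares (`scipy.optimize.least_squares`); the
result is verified through the forward computations at ±0.5 mV for
potentials and ±2% for currents and conductances, and calibration fails
loudly otherwise.

The resting MT current target is referenced to −84 mV rather than to the
cell's resting potential. The measured basal numbers are mutually
inconsistent under the latter reading: 70 pA at −65.8 mV implies ≈ 1.06 nS
of MT conductance, which forces the conductance between the two measured
resting potentials to ≈ 11.9 nS while the measured slope at −64 mV is
10.0 nS — no monotone activation model closes that gap. At −84 mV every
constraint is simultaneously satisfiable.

## Simulation

Voltage-clamp step families assume an ideal clamp (no series-resistance
error) and piecewise-constant commands, so each gating variable relaxes
exponentially within a segment and is propagated *exactly* — no ODE error.
Current-clamp protocols integrate the full system with `solve_ivp`
(LSODA, rtol 1e-7, atol 1e-8), segment-by-segment so stimulus
discontinuities never cross an integration step, with the step size capped
at a twentieth of the sine period during sinusoidal segments. Initial
conditions are the steady state at the stimulus' initial value.

Responses are computed on an internal grid oversampled ≥ 5× for 5 kHz step
protocols (sound-like protocols already run at 100 kHz), low-pass filtered
with an 8-pole Bessel at half the protocol sample rate (capped at 20 kHz),
and decimated to the protocol rate — emulating the recording chain's
anti-alias filter. Filtering is zero-phase (forward–backward), a documented
deviation from causal acquisition hardware chosen so that filtering cannot
introduce artificial timing delays into the phase analyses. Gaussian
recording noise (6 pA VC, 0.12 mV CC — typical whole-cell trace noise at
these bandwidths) is added after integration, reproducibly under a seed.
Ordering comparisons (timing leads, linopirdine phenotype) are run
noise-free, as single-trial peak jitter at 2 kHz exceeds the few-µs
systematic timing differences; the experimental analogue is averaging
across cells before differencing.

## Measurement procedures

* **I-V**: peak current = the sample nearest 2 ms after step onset (the
  fast BK current is the only component settled by then); steady state =
  10 ms mean centred on 160 ms. Absolute currents; the holding current is
  not subtracted. Slope conductance = least-squares line through the points
  within ±10 mV of the operating potential.
* **Tail activation**: a single exponential is fitted to each tail over
  [onset + 0.3 ms, onset + 10 ms] and evaluated at tail onset (the
  "instantaneous" amplitude, immune to the clamp-settling artifact); the
  curve of amplitudes vs preceding step potential is fitted with a rising
  first-order Boltzmann with offset, initialized deterministically
  (V_half at the half-range crossing, S at a quarter of the span). The fit
  uses power 1 regardless of the generator's power.
* **Onset τ**: single exponential from step onset to the first response
  peak, τ initialized at the 63% crossing.
* **AC/DC**: per-cycle mean (DC, reported at cycle centres with the
  pre-onset resting potential for shift computation) and per-cycle
  peak-to-peak of the mean-subtracted cycle (AC). For a symmetric current
  sine the model's sustained DC is near zero; the depolarizing, graded DC
  of basal cells is the onset transient (time scale = membrane time
  constant), so DC gradedness is assessed over the first ~1.5 ms.
* **Extrema / timing**: one extremum per stimulus half cycle, windows
  phase-referenced to the sine onset but shifted by T/8 so response lags of
  up to 135° stay in their window; 3-point parabolic refinement of the
  peak time; plateau edges and flat windows are flagged absent. Equivalent
  peaks are matched by half-cycle index and kind (with a one-window borrow
  for lags beyond a half cycle), never by greedy nearest-neighbour. Phase
  angle = 360·f·Δt identically. Half-cycle-width error is the *signed*
  percentage deviation from 1/(2f) (0 = perfect); an absolute variant is
  exported alongside.
* **Release**: `P(V) = [1 + exp((V_half − V)/S)]^(−1)` with V_half/S =
  −25.8/5.5 mV (apical) and −31.4/7.7 mV (basal); the printed "mV⁻¹" on S
  is read as a typographical artifact — S is a slope factor in mV. The
  transform is instantaneous and memoryless (steady-state transfer
  function; no vesicle-pool dynamics).

## Shipped protocol defaults

Current-clamp steps: 100 pA increments, −100 → +900 pA, 160 ms steps.
Voltage-clamp steps: 10 mV increments, −144 → +36 mV (the upper bound is a
configurable default; it is not a measured fact), holding −64 mV, 170 ms
steps (so the 160 ms point exists), 50 ms tails at −124 mV, 5 kHz.
Sound-like sine: given peak-to-peak amplitude ("1 nA" stimuli are 1 nA
peak-to-peak) on a holding current equal to the resting MT current (500 pA
apical / 50 pA basal), phase 0 rising at onset, 40 ms pre/post, ≥ 15 cycles,
100 kHz. The 6 nA maximal protocol uses holding = half the peak-to-peak
(3 nA), so the injected current swings 0 → 6 nA like a fully modulated
maximal MT current; segment durations are configurable defaults, not
measured facts. Fluid jet: 50 Hz, ≤ ±20 V driver, 8-pole Bessel at 0.5 kHz.

## What the synthetic data does and does not emulate

The generator reproduces: the steady-state operating points and slope
conductances of both cell types in both Ca²⁺ conditions; blocker
pharmacology by conductance class; MT saturation and resting-current
behaviour under bundle stimulation and under DHS; membrane-time-constant
filtering of sound-like stimuli and its consequences (AC roll-off with
frequency, apical timing lead, onset-transient DC); additive recording
noise and the acquisition anti-alias chain.

It does not emulate: series-resistance and capacitance-transient artifacts
of real voltage clamp; stochastic channel gating; MT adaptation or bundle
mechanics; inactivation; temperature effects; vesicle-pool dynamics; or
cell-to-cell variability (each preset is one "average" cell). Passing
tests therefore demonstrate internal consistency of the measurement
procedures and calibrated operating points, not that real recordings would
produce these exact waveforms.

## Numerical choices and degenerate inputs

Root finding for the resting potential brackets on a 1 mV scan of
[−150, +50] mV and polishes with Brent's method (the first crossing from
hyperpolarized is taken; shipped presets are monostable). Tail and onset
exponential fits fall back (tails: 0.5 ms mean, flagged in metadata) or
raise (onsets) when degenerate. Flat traces yield "absent" extrema rather
than errors; downstream statistics skip absent indices. Windows are
half-open `[start, end)`; the sweep time origin is 0. Protocol/serialization
round trips are bit-exact (HDF5 container, schema version 1).

## Problem sizes

All shipped analyses run at the protocols' native sizes: 19-sweep voltage
families at 5 kHz, 100 kHz sound-like sweeps of 30–90 ms, 500 ms
resting-potential confirmations, 100-replicate Monte-Carlo τ-fit checks.
The full test suite and the acceptance script each complete in seconds.
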