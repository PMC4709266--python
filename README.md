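# ihc-encode

Conductance-based simulation and patch-clamp analysis of how mammalian
cochlear inner hair cells (IHCs) are intrinsically specialized for
**frequency** (phase-locked, low-CF apical cells) versus **intensity**
(sustained, high-CF basal cells) encoding.

Low-frequency (~0.3 kHz, apical) and high-frequency (~30 kHz, basal) gerbil
IHCs differ in their resting mechanotransducer (MT) current, resting
membrane potential, K⁺-conductance complement, and membrane time constant.
This package provides, for people who analyze or model hair-cell
electrophysiology:

* a **single-compartment IHC model** — BK-type `I_K,f`, negatively
  activating KCNQ-type `I_K,n`, a more positively activating
  linopirdine-sensitive conductance, slow `I_K,s`, ohmic leak, and a
  Boltzmann MT channel whose resting open probability depends on
  extracellular Ca²⁺ — with calibrated apical and basal presets and
  composable pharmacology (DHS, linopirdine, iberiotoxin);
* the **stimulus protocols**: current/voltage step families, sound-like
  sinewaves on holding currents, fluid-jet bundle drives, with Bessel
  anti-alias filtering and realistic sampling;
* the **measurement procedures**: I-V extraction (2 ms peak / 160 ms steady
  state), slope conductance, tail-current activation curves and Boltzmann
  fits, pharmacological subtraction, holding-current shifts, junction and
  clamp-time-constant corrections, onset time-constant fits, AC/DC
  decomposition, per-half-cycle extrema, equivalent-peak timing and
  half-cycle-width errors;
* the **synaptic transfer**: Boltzmann transform of membrane potential into
  vesicle release probability, `P(V) = [1 + exp((V½ − V)/S)]⁻¹`
  (apical V½ = −25.8 mV, S = 5.5 mV; basal V½ = −31.4 mV, S = 7.7 mV).

The membrane model is `C_m dV/dt = I_inj − Σ g_x q_x (V − E_K) −
g_leak(V − E_leak) − g_MT Po (V − E_MT)` with first-order gating
`dq/dt = (q_∞(V) − q)/τ(V)`, `q_∞ = [1 + exp((V½ − V)/S)]⁻¹`, and a
bell-shaped τ(V). See `docs/methods.md` for the full model, calibration
scheme, and limitations.

## Worked example

```python
import numpy as np
from ihc_encode import get_preset, simulate, steady_state_vm, make_condition
from ihc_encode.protocols import make_vc_steps, make_sine_protocol
from ihc_encode import vc_analysis as vca, cc_analysis as cca

apical = get_preset("apical")   # loads base parameters and calibrates
basal = get_preset("basal")

# resting potentials in standard (1.3 mM) and endolymph-like (40 µM) Ca²⁺
for p in (apical, basal):
    for ca in ("Ca1.3", "lowCa40"):
        v = steady_state_vm(p, make_condition(ca), I_inj=0.0)
        print(f"{p.label:6s} rest in {ca}: {v:6.1f} mV")

# voltage-clamp step family -> steady-state I-V -> slope conductance
sweeps = simulate(apical, "Ca1.3", make_vc_steps(), seed=1)
iv = vca.measure_iv(sweeps, "ss_160ms")
g = vca.slope_conductance(iv, V0=-54.0)
print(f"apical slope conductance at -54 mV: {g:.1f} nS")

# 2 kHz sound-like stimulation: equivalent-peak timing, apical vs basal
proto = make_sine_protocol(2000.0, 1000.0, 500.0, sine_duration=5.0)
resp_a = simulate(apical, "Ca1.3", proto, noise=False).responses[0]
resp_b = simulate(basal, "Ca1.3", proto, noise=False).responses[0]
ea = cca.detect_extrema(resp_a, 2000.0, proto.sine_onset)
eb = cca.detect_extrema(resp_b, 2000.0, proto.sine_onset)
stats = cca.timing_difference(ea, eb)
dt = np.mean([v for k, v in stats.delta_t if k >= 2])
print(f"basal delay re apical at 2 kHz: {dt*1e3:.1f} us "
      f"({360*2000*dt*1e-3:.2f} deg)")
```

prints

```
apical rest in Ca1.3:  -68.6 mV
apical rest in lowCa40:  -56.1 mV
basal  rest in Ca1.3:  -71.6 mV
basal  rest in lowCa40:  -65.9 mV
apical slope conductance at -54 mV: 56.4 nS
basal delay re apical at 2 kHz: 3.9 us (2.78 deg)
```

Low Ca²⁺ (which raises the MT resting open probability) depolarizes the
apical cell by ~12.5 mV but the basal cell by only ~5.7 mV; the apical
cell's much larger resting conductance (56 vs 10 nS slope) shortens its
membrane time constant, and its response peaks lead the basal cell's at
every stimulus cycle — the biophysical basis of its phase-locking
advantage.

There is also a CLI (`ihc-encode simulate / analyze-vc / analyze-cc /
release / run / selftest`) for scripted pipelines; see `ihc-encode --help`.

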