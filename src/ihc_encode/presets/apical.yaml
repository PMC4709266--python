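# Apical (low-frequency, ~0.3 kHz) inner hair cell preset.
#
# Base parameters before calibration.  Conductance scalings, the leak and the
# MT resting open probabilities are refined by calibrate() against the
# measured targets listed at the bottom: resting potentials in the two Ca2+
# conditions, resting MT current in endolymph-like low Ca2+ (referenced to
# the -84 mV holding potential of the MT-current recordings), and the
# steady-state slope conductance near the in vivo operating point.
#
# Gating kinetics are fixed design values: the BK-type K_f settles well
# before the 2 ms peak measurement and activates positive to the slope
# window; K_n_neg activates very negatively (V_half -85 mV) and dominates
# the resting conductance together with the apical-only, more positively
# activating linopirdine-sensitive K_n_pos, which carries most of the apical
# delayed outward current near -54 mV; K_s is a slow, positively activating
# delayed rectifier.
label: apical
C_m_pF: 12.4
E_K_mV: -82.0
noise_sd_vc_pA: 6.0
noise_sd_cc_mV: 0.12
conductances:
  - name: K_f
    g_max_nS: 18.0
    E_rev_mV: -82.0
    gating: {V_half: -45.0, S: 7.0, power: 1,
             tau_base: 0.15, tau_amp: 0.25, tau_Vhalf: -60.0, tau_sigma: 30.0}
  - name: K_n_pos
    g_max_nS: 65.0
    E_rev_mV: -82.0
    gating: {V_half: -42.0, S: 9.0, power: 1,
             tau_base: 1.5, tau_amp: 6.0, tau_Vhalf: -55.0, tau_sigma: 25.0}
  - name: K_n_neg
    g_max_nS: 5.0
    E_rev_mV: -82.0
    gating: {V_half: -85.0, S: 9.0, power: 1,
             tau_base: 3.0, tau_amp: 17.0, tau_Vhalf: -90.0, tau_sigma: 30.0}
  - name: K_s
    g_max_nS: 3.0
    E_rev_mV: -82.0
    gating: {V_half: -5.0, S: 12.0, power: 1,
             tau_base: 8.0, tau_amp: 15.0, tau_Vhalf: -40.0, tau_sigma: 30.0}
  - name: leak
    g_max_nS: 4.0
    E_rev_mV: -40.0
    gating: null
mt:
  g_MT_max_nS: 13.0        # saturating MT current ~1.1 nA at -84 mV
  E_MT_mV: 0.0
  x0: 1.8
  sx: 0.8
  resting_Po: {Ca1.3: 0.004, lowCa40: 0.42}
calibration_targets:
  v_rest: {Ca1.3: -68.6, lowCa40: -56.1}
  mt_rest_pA: 464.0
  mt_measure_mV: -84.0
  slope_nS: 56.3
  slope_at_mV: -54.0
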