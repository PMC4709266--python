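# Basal (high-frequency, ~30 kHz) inner hair cell preset.
#
# Differs from the apical preset in its much smaller MT resting open
# probability, a near-absent positively activating linopirdine-sensitive
# conductance (K_n_pos), a larger negatively activating K_n_neg, and a larger
# slow delayed rectifier K_s that carries the basal outward current at
# depolarized potentials.  Calibration targets as in apical.yaml.
label: basal
C_m_pF: 11.7
E_K_mV: -82.0
noise_sd_vc_pA: 6.0
noise_sd_cc_mV: 0.12
conductances:
  - name: K_f
    g_max_nS: 10.0
    E_rev_mV: -82.0
    gating: {V_half: -22.0, S: 7.0, power: 1,
             tau_base: 0.15, tau_amp: 0.25, tau_Vhalf: -60.0, tau_sigma: 30.0}
  - name: K_n_pos
    g_max_nS: 0.1
    E_rev_mV: -82.0
    gating: {V_half: -52.0, S: 9.0, power: 1,
             tau_base: 1.5, tau_amp: 6.0, tau_Vhalf: -55.0, tau_sigma: 25.0}
  - name: K_n_neg
    g_max_nS: 6.0
    E_rev_mV: -82.0
    gating: {V_half: -85.0, S: 9.0, power: 1,
             tau_base: 3.0, tau_amp: 17.0, tau_Vhalf: -90.0, tau_sigma: 30.0}
  - name: K_s
    g_max_nS: 8.0
    E_rev_mV: -82.0
    gating: {V_half: -5.0, S: 12.0, power: 1,
             tau_base: 8.0, tau_amp: 15.0, tau_Vhalf: -40.0, tau_sigma: 30.0}
  - name: leak
    g_max_nS: 2.3
    E_rev_mV: -51.0
    gating: null
mt:
  g_MT_max_nS: 12.0        # saturating MT current ~1.0 nA at -84 mV
  E_MT_mV: 0.0
  x0: 1.8
  sx: 0.8
  resting_Po: {Ca1.3: 0.005, lowCa40: 0.069}
calibration_targets:
  v_rest: {Ca1.3: -71.7, lowCa40: -65.8}
  mt_rest_pA: 70.0
  mt_measure_mV: -84.0
  slope_nS: 10.0
  slope_at_mV: -64.0
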