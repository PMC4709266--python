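# Voltage-clamp characterization of the basal preset:
#   ihc-encode run --config examples/vc_steps_basal.yaml --out results/vc_basal
preset: basal
condition: Ca1.3
seed: 1
protocol:
  kind: vc_steps            # -144 -> +36 mV, 10 mV steps, tail -124 mV
analysis:
  slope_at_mV: [-64.0]
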