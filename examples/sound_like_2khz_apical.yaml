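# Sound-like 2 kHz stimulation of the apical preset, with timing and
# release-probability tables:
#   ihc-encode run --config examples/sound_like_2khz_apical.yaml --out results/sine_apical
preset: apical
condition: Ca1.3
seed: 1
protocol:
  kind: sine
  frequency: 2000Hz
  peak_to_peak: 1000pA      # "1 nA" stimuli are peak-to-peak
  holding: 500pA            # the apical resting MT current
  pre_duration: 40
  sine_duration: 50
  post_duration: 40
analysis:
  release: true
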