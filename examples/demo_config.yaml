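# Two simulated trial years over the six preset cultivar behaviours.
# Run:  windlodge simulate --config examples/demo_config.yaml -o scratch/demo
seed: 20160909
s_max: 30
profile: identity   # thresholds are calibrated against the generated speed
years: [2016, 2017]
cultivars:
  - preset: unimodal_20
  - preset: unimodal_26
  - preset: bimodal_12_24
  - preset: bimodal_20_30
  - preset: mostly_censored
  - preset: mostly_censored_tail
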