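# Fully worked scenario configuration for `rdnasim simulate`.
#
#   rdnasim simulate --config examples/panels.yaml --seed 1 --out run1/
#
# Each entry under `scenarios` maps a label to ScenarioParams fields;
# omitted fields take the documented defaults (28 divisions, 10 GSCs,
# 100 flies, 16 sperm per division).  Unknown keys are an error.
# `comparisons` requests shift-equivalence tests between scenario pools.

scenarios:
  nonmagnifying:
    initial_cn: 200
    usce_freq_gsc: 0.04
    usce_freq_sg: 0.0
    gsc_gain_bias: 0.5

  gsc-usce-bias80:
    initial_cn: 100
    usce_freq_gsc: 0.5
    usce_freq_sg: 0.0
    gsc_gain_bias: 0.8

  gsc-sg-usce-bias80:
    initial_cn: 100
    usce_freq_gsc: 0.5
    usce_freq_sg: 0.5
    gsc_gain_bias: 0.8

comparisons:
  - x: gsc-usce-bias80
    y: gsc-sg-usce-bias80
    margin: 1
    threshold: 0.95
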