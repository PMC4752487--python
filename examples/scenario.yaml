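# One desk-scale design cell per generating distribution, binary fixed effect.
# Strengths are given explicitly here so the run skips calibration; delete a
# "strength" line to calibrate that scenario to ~10% false negatives instead.
seed: 1
n_datasets: 100
out: results
scenarios:
  - effect_type: fixed_categorical
    family: poisson
    strength: 0.55
  - effect_type: fixed_categorical
    family: negbinom
    k: 10.0
    strength: 0.6
  - effect_type: fixed_categorical
    family: lognormal_poisson
    sd: 0.36
    strength: 0.6
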