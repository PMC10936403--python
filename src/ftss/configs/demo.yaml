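# End-to-end demonstration run: simulated 168-subject cohort, 3 trials per
# subject, both sensor locations; models fit on the torso features, pooled.
seed: 1
n_subjects: 168
n_trials: 3
sensors: [torso, thigh]
fit_sensors: [torso]
low_hz: 0.01
high_hz: 5.0
trim_s: 1.0
pos_threshold_frac: 0.4
neg_threshold_frac: 0.5
thigh_midstand_frac: 0.8
min_cycle_separation_s: 0.5
k_folds: 10
interactions: true
classification_outcomes: [balance, cognition, falls]
regression_outcomes: [bbs, mmse]
stratum: pooled
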