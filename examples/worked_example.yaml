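# Five-dose migraine-style worked example: K experimental arms vs placebo,
# unequal stage sizes, known response SD, one-sided familywise level 0.025.
design:
  n_arms: 5
  m1: 28
  m2: 140
  futility_threshold: 0.0
  sigma: 5.0
  alpha: 0.025
scenario:
  kind: permutation
  gammas: [0.75, 0.8125, 0.875, 0.9375]
  delta: 2.0
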