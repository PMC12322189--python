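# Base model: one shared lineup-fairness parameter b; dP, g, dA free per
# condition; suspect-sampling constant for six-person lineups.
equal:
  b: all
sampling_constant: 0.16667
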