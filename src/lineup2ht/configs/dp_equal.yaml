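# Null model: culprit-presence detection dP equated across all conditions
# (in addition to the base model's shared b).
equal:
  b: all
  dP: all
sampling_constant: 0.16667
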