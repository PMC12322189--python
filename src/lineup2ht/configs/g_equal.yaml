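# Null model: guessing-based selection g equated across all conditions.
equal:
  b: all
  g: all
sampling_constant: 0.16667
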