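# Bondi van der Waals radii (Angstrom), version 1.
# Source values are the standard Bondi compilation as used across
# structural chemistry; extend here if exotic elements appear.
version: 1
radii:
  H: 1.20
  C: 1.70
  N: 1.55
  O: 1.52
  F: 1.47
  P: 1.80
  S: 1.80
  Cl: 1.75
  Se: 1.90
  Br: 1.85
  I: 1.98
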