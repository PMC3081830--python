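method: 'B97-D/TZVP (text)'
r_factor: 0.087
classes:
  nonpolar: {mu: -0.29, sigma2: 0.02, n: 0}
  polar: {mu: 0.59, sigma2: 1.58, n: 0}
  all: {mu: 0.2, sigma2: 1.06, n: 0}
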