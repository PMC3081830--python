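method: 'GAFF'
r_factor: 0.127
classes:
  nonpolar: {mu: 0.25, sigma2: 0.36, n: 0}
  polar: {mu: 0.46, sigma2: 5.64, n: 0}
  all: {mu: 0.36, sigma2: 3.26, n: 0}
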