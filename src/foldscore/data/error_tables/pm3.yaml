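method: 'PM3'
r_factor: 0.352
classes:
  nonpolar: {mu: 0.14, sigma2: 0.77, n: 0}
  polar: {mu: 4.67, sigma2: 4.59, n: 0}
  all: {mu: 2.65, sigma2: 7.89, n: 0}
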