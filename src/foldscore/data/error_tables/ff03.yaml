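method: 'FF03'
r_factor: 0.259
classes:
  nonpolar: {mu: 0.18, sigma2: 0.81, n: 0}
  polar: {mu: 1.36, sigma2: 10.86, n: 0}
  all: {mu: 0.83, sigma2: 6.61, n: 0}
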