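method: 'MP2/aTZ'
r_factor: 0.023
classes:
  nonpolar: {mu: 0.05, sigma2: 0.0, n: 0}
  polar: {mu: 0.24, sigma2: 0.02, n: 0}
  all: {mu: 0.16, sigma2: 0.02, n: 0}
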