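method: 'HF/aTZ'
r_factor: 0.171
classes:
  nonpolar: {mu: 2.28, sigma2: 1.1, n: 0}
  polar: {mu: 1.95, sigma2: 1.17, n: 0}
  all: {mu: 2.1, sigma2: 1.17, n: 0}
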