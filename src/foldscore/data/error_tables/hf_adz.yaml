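method: 'HF/aDZ'
r_factor: 0.176
classes:
  nonpolar: {mu: 2.29, sigma2: 1.11, n: 0}
  polar: {mu: 2.02, sigma2: 1.29, n: 0}
  all: {mu: 2.14, sigma2: 1.22, n: 0}
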