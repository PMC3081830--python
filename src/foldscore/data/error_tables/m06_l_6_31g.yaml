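method: 'M06-L/6-31G*'
r_factor: 0.103
classes:
  nonpolar: {mu: 0.4, sigma2: 0.1, n: 0}
  polar: {mu: 0.96, sigma2: 0.57, n: 0}
  all: {mu: 0.71, sigma2: 0.43, n: 0}
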