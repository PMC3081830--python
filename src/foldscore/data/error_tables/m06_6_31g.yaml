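method: 'M06/6-31G*'
r_factor: 0.104
classes:
  nonpolar: {mu: 0.63, sigma2: 0.12, n: 0}
  polar: {mu: 0.85, sigma2: 0.64, n: 0}
  all: {mu: 0.75, sigma2: 0.42, n: 0}
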