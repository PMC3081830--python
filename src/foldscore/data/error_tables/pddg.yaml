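method: 'PDDG'
r_factor: 0.484
classes:
  nonpolar: {mu: -0.62, sigma2: 0.9, n: 0}
  polar: {mu: 6.3, sigma2: 7.48, n: 0}
  all: {mu: 3.21, sigma2: 16.23, n: 0}
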