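method: 'AM1'
r_factor: 0.373
classes:
  nonpolar: {mu: 1.04, sigma2: 0.7, n: 0}
  polar: {mu: 4.85, sigma2: 10.28, n: 0}
  all: {mu: 3.15, sigma2: 9.5, n: 0}
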