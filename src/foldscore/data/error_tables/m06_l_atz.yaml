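method: 'M06-L/aTZ'
r_factor: 0.096
classes:
  nonpolar: {mu: 0.55, sigma2: 0.07, n: 0}
  polar: {mu: 0.91, sigma2: 0.14, n: 0}
  all: {mu: 0.75, sigma2: 0.14, n: 0}
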