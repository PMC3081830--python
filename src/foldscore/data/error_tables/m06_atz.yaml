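method: 'M06/aTZ'
r_factor: 0.09
classes:
  nonpolar: {mu: 0.57, sigma2: 0.08, n: 0}
  polar: {mu: 0.85, sigma2: 0.19, n: 0}
  all: {mu: 0.73, sigma2: 0.16, n: 0}
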