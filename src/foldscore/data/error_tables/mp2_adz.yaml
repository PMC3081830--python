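method: 'MP2/aDZ'
r_factor: 0.061
classes:
  nonpolar: {mu: 0.21, sigma2: 0.01, n: 0}
  polar: {mu: 0.69, sigma2: 0.19, n: 0}
  all: {mu: 0.48, sigma2: 0.16, n: 0}
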