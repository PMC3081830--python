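method: 'MP2/6-31G*'
r_factor: 0.146
classes:
  nonpolar: {mu: 1.12, sigma2: 0.28, n: 0}
  polar: {mu: 1.34, sigma2: 0.91, n: 0}
  all: {mu: 1.24, sigma2: 0.64, n: 0}
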