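method: 'FF99SB'
r_factor: 0.17
classes:
  nonpolar: {mu: 0.12, sigma2: 1.27, n: 0}
  polar: {mu: 1.22, sigma2: 5.83, n: 0}
  all: {mu: 0.73, sigma2: 4.04, n: 0}
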