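method: 'PM6-DH2'
r_factor: 0.071
classes:
  nonpolar: {mu: -0.09, sigma2: 0.1, n: 0}
  polar: {mu: 0.62, sigma2: 1.95, n: 0}
  all: {mu: 0.3, sigma2: 1.23, n: 0}
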