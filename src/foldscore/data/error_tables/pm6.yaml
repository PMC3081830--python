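method: 'PM6'
r_factor: 0.211
classes:
  nonpolar: {mu: 0.84, sigma2: 0.32, n: 0}
  polar: {mu: 2.34, sigma2: 2.82, n: 0}
  all: {mu: 1.67, sigma2: 2.24, n: 0}
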