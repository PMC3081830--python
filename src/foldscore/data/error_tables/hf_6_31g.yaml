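method: 'HF/6-31G*'
r_factor: 0.153
classes:
  nonpolar: {mu: 2.27, sigma2: 1.14, n: 0}
  polar: {mu: 1.68, sigma2: 1.3, n: 0}
  all: {mu: 1.94, sigma2: 1.32, n: 0}
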