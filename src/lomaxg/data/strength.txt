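0.55 0.74 0.77 0.81 0.84 1.24 0.93 1.04 1.11 1.13 1.30 1.25
1.27 1.28 1.29 1.48 1.36 1.39 1.42 1.48 1.51 1.49 1.49 1.50
1.50 1.55 1.52 1.53 1.54 1.55 1.61 1.58 1.59 1.60 1.61 1.63
1.61 1.61 1.62 1.62 1.67 1.64 1.66 1.66 1.66 1.70 1.68 1.68
1.69 1.70 1.78 1.73 1.76 1.76 1.77 1.89 1.81 1.82 1.84 1.84
2.00 2.01 2.24
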