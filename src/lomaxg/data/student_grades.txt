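29 25 50 15 13 27 15 18 7 7 8 19
12 18 5 21 15 86 21 15 14 39 15 14
70 44 6 23 58 19 50 23 11 6 34 18
28 34 12 37 4 60 20 23 40 65 19 31
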