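0.040 1.866 2.385 3.443 0.301 1.876 2.481 3.467 0.309 1.899 2.610 3.478
0.557 1.911 2.625 3.578 0.943 1.912 2.632 3.595 1.070 1.914 2.646 3.699
1.124 1.981 2.661 3.779 1.248 2.010 2.688 3.924 1.281 2.038 2.823 4.035
1.281 2.085 2.890 4.121 1.303 2.089 2.902 4.167 1.432 2.097 2.934 4.240
1.480 2.135 2.962 4.255 1.505 2.154 2.964 4.278 1.506 2.190 3.000 4.305
1.568 2.194 3.103 4.376 1.615 2.223 3.114 4.449 1.619 2.224 3.117 4.485
1.652 2.229 3.166 4.570 1.652 2.300 3.344 4.602 1.757 2.324 3.376 4.663
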