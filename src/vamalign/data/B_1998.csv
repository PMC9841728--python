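0.685,0.288,0.142,0.09503,0.0681
0.2001,0.417,0.264,0.126,0.0784
0.07009,0.194,0.377,0.285,0.112
0.0245,0.0631,0.142,0.293,0.2205
0.0193,0.0367,0.0741,0.199,0.52004
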