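0.944,0.175,0.00412,0.000000788
0.0209,0.778,0.325,0.000000832
0.0140,0.0125,0.582,0.302
0.0119,0.0110,0.0825,0.289
0.00898,0.0231,0.00531,0.407
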