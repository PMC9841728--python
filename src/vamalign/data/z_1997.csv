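prob
0.505
0.226
0.122
0.0663
0.0797
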