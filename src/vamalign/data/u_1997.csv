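prob
0.4502
0.251
0.117
0.179
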