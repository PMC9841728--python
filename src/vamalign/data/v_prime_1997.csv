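prob
0.4307
0.235
0.156
0.0857
0.0911
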