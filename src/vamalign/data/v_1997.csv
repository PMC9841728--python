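prob
0.469
0.243
0.132
0.070008
0.0839
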