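prob
0.491
0.233
0.104
0.1701
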