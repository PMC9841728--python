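0.686,0.342,0.161,0.0915
0.19002,0.374,0.283,0.124
0.0721,0.183,0.313,0.227
0.0288,0.0613,0.143,0.224
0.0223,0.0388,0.0975,0.332
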