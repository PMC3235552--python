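D3.32
Y3.33
C3.36
E5.46
Y6.51
F7.39
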