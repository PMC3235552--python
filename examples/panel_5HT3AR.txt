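E129
Y141
Y143
Y153
W183
W195
Y234
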