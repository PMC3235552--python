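fragment_id,target_id,pki
frag01,H4R,7.0
frag02,H4R,6.2
frag03,H4R,6.7
frag04,5HT3AR,6.1
frag05,5HT3AR,6.0
frag06,5HT3AR,6.1
frag07,H4R,6.2
frag07,5HT3AR,6.6
frag08,H4R,7.2
frag08,5HT3AR,7.9
frag09,H4R,6.1
frag09,5HT3AR,8.8
frag10,H4R,8.2
frag10,5HT3AR,5.9
frag11,H4R,6.2
frag11,5HT3AR,5.9
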