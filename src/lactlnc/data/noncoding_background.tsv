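base	freq
A	0.32
C	0.18
G	0.18
T	0.32
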