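step,volume_ml
1,0.039
2,0.077
3,0.154
4,0.307
5,0.614
6,1.228
7,2.456
8,4.912
9,9.824
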