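factor,S1,S2,S3,S4,S5,S6,S7,S8,S9,S10,S11,S12,S13,S14
S1,-,X,V,V,V,O,V,V,A,A,V,O,V,V
S2,-,-,V,V,O,V,V,O,A,A,V,V,V,V
S3,-,-,-,A,V,A,A,O,A,A,A,A,A,A
S4,-,-,-,-,V,A,A,A,A,O,A,A,X,V
S5,-,-,-,-,-,O,A,A,A,A,A,A,A,O
S6,-,-,-,-,-,-,A,A,A,A,X,A,V,A
S7,-,-,-,-,-,-,-,A,A,O,O,V,V,V
S8,-,-,-,-,-,-,-,-,A,A,O,O,O,V
S9,-,-,-,-,-,-,-,-,-,X,V,O,V,V
S10,-,-,-,-,-,-,-,-,-,-,V,V,V,O
S11,-,-,-,-,-,-,-,-,-,-,-,X,V,V
S12,-,-,-,-,-,-,-,-,-,-,-,-,V,V
S13,-,-,-,-,-,-,-,-,-,-,-,-,-,A
S14,-,-,-,-,-,-,-,-,-,-,-,-,-,-
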