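group,rank,cc
G1,1,CC01
G1,2,CC02
G1,3,CC03
G2,1,CC04
G2,2,CC05
G3,1,CC06
G3,2,CC07
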