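cc
CC08
CC09
CC10
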