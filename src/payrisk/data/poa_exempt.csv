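code
D002
D010
D022
D030
D045
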