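# planted "drivers" of the tiny fixture
GENE1
GENE4
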