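chr22	42721250	42721280	STAT1_A4GALT
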