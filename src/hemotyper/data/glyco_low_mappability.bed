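chr4	143800000	143804800	GYPE_lowmap
chr4	144040000	144043200	intergenic_lowmap
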