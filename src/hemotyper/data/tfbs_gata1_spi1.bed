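chr11	47371000	47371020	GATA1_SPI1
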