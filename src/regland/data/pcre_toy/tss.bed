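chrT	10000	10001	geneA
chrT	50000	50001	geneB
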