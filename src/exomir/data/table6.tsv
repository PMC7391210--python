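miRNA	tumor_readcount	normal_readcount	log2FoldChange	pvalue
hsa-miR-941	935.950365	451.2506521	1.0388	1.25E-09
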