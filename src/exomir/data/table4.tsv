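miRNA	auc	se	pvalue	ci_low	ci_high
miR-941	0.797	0.062	<0.001	0.676	0.918
miR-27a-5p	0.672	0.067	0.016	0.540	0.804
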