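method	printed_rank	gene	statistic	extra
bestkeeper	1	U6	0.46	1.74
bestkeeper	2	miR-30a-5p	0.6	2.63
bestkeeper	3	miR-532-5p	0.6	2.03
bestkeeper	4	miR-181a-5p	0.62	2.08
bestkeeper	5	miR-425-5p	0.78	2.88
bestkeeper	6	miR-363-3p	0.84	3.68
bestkeeper	7	miR-424-3p	0.89	2.96
bestkeeper	8	miR-181b-5p	0.98	3.74
bestkeeper	9	miR-16-5p	1.04	4.69
normfinder	1	miR-532-5p	0.509
normfinder	2	miR-30a-5p	0.654
normfinder	3	miR-181a-5p	0.824
normfinder	4	U6	0.831
normfinder	5	miR-363-3p	0.871
normfinder	6	miR-425-5p	1.005
normfinder	7	miR-424-3p	1.088
normfinder	8	miR-181b-5p	1.196
normfinder	9	miR-16-5p	1.396
genorm	1	miR-30a-5p	0.614
genorm	2	miR-181a-5p	0.614
genorm	3	U6	0.951
genorm	4	miR-532-5p	1.012
genorm	5	miR-363-3p	1.082
genorm	6	miR-425-5p	1.147
genorm	7	miR-424-3p	1.192
genorm	8	miR-181b-5p	1.247
genorm	9	miR-16-5p	1.335
delta_ct	1	miR-532-5p	1.12
delta_ct	2	miR-30a-5p	1.17
delta_ct	3	miR-181a-5p	1.25
delta_ct	4	U6	1.27
delta_ct	5	miR-363-3p	1.28
delta_ct	6	miR-425-5p	1.37
delta_ct	7	miR-424-3p	1.42
delta_ct	8	miR-181b-5p	1.49
delta_ct	9	miR-16-5p	1.64
reffinder	1	miR-30a-5p	1.68
reffinder	2	miR-532-5p	1.86
reffinder	3	miR-181a-5p	2.45
reffinder	4	U6	2.63
reffinder	5	miR-363-3p	5.23
reffinder	6	miR-425-5p	5.73
reffinder	7	miR-424-3p	7
reffinder	8	miR-181b-5p	8
reffinder	9	miR-16-5p	9
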