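library_id	depth_label	na_type	n_reads	mean_length_bp	total_length_mb	gc_percent	n_rrna_reads
ss_0-2	0-2	ssDNA	1091418	230.5	251	52.1	1
ds_0-2	0-2	dsDNA	751300	226.6	170	61.1	0
ss_5-8	5-8	ssDNA	725380	222.2	161	54.5	0
ds_5-8	5-8	dsDNA	647462	223.4	145	62.8	1
ss_10-15	10-15	ssDNA	213547	211.8	45	47.7	0
ds_10-15	10-15	dsDNA	271392	218.1	59	52.7	0
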