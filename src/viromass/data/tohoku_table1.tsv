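sample_id	depth_top_cm	depth_bottom_cm	cells_per_cm3	cells_sd	viruses_per_cm3	viruses_sd	ssdna_ng_per_cm3	dsdna_ng_per_cm3
T0-2	0	2	9.1e6	1.1e6	5.3e6	1.8e6	2.87	0.29
T5-8	5	8	5.9e6	1.2e6	2.8e6	0.2e6	1.69	0.26
T10-15	10	15	1.6e6	0.9e6	5.1e5	1.7e5	1.50	0.17
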