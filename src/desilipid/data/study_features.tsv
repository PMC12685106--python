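comparison	relative_abundance	observed_mz	theoretical_mz	expected_name	isotope_offset	q_value	fold_change
cancer_vs_benign	up_tumor	688.4921	688.4923	PE 32:1	0	5.7e-6	1.24
cancer_vs_benign	up_tumor	699.5014	699.4970	PA 36:2	0	1.2e-6	1.27
cancer_vs_benign	up_tumor	714.5123	714.5079	PE 34:2	0	6.8e-7	1.28
cancer_vs_benign	up_tumor	740.5229	740.5236	PE 36:3	0	1.4e-6	1.27
cancer_vs_benign	up_tumor	864.5707	864.5760	PS 42:5	0	4.1e-5	1.24
cancer_vs_benign	up_tumor	913.5778	913.5812	PI 40:4	0	1.1e-5	1.23
cancer_vs_benign	up_tumor	915.5901	915.5968	PI 40:3	0	1.8e-7	1.27
highrisk_vs_lowrisk_benign	up_high_risk	753.5636	753.5633	PE O-38:4	1	0.0241	4.03
highrisk_vs_lowrisk_benign	up_high_risk	813.5425	813.5481	PS 38:3	1	0.0227	3.09
highrisk_vs_lowrisk_benign	up_high_risk	839.5628	839.5637	PS 40:4	1	0.0154	10.97
highrisk_vs_lowrisk_benign	up_high_risk	890.5829	890.5917	PS 44:6	0	0.0309	5.06
highrisk_vs_lowrisk_cancer	up_low_risk	714.5123	714.5079	PE 34:2	0	0.0225	1.84
highrisk_vs_lowrisk_cancer	up_low_risk	740.5229	740.5236	PE 36:3	0	0.0444	1.63
highrisk_vs_lowrisk_cancer	up_low_risk	753.5636	753.5633	PE O-38:4	1	0.0482	1.69
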