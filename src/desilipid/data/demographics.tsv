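variable	level	cancer	benign
menopause	premenopausal	7	6
menopause	postmenopausal	43	8
diabetes	non_diabetic	40	13
diabetes	diabetic	10	1
smoking	non_or_former_smoker	46	14
smoking	current_smoker	4	0
family_history	no_first_degree	31	11
family_history	first_degree	19	3
bmi	normal	11	6
bmi	overweight_obese	39	8
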