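name	lipid_class	adduct	theoretical_mz	msms_note
PE 32:1	PE	[M-H]-	688.4923	PE (16:1_16:0)/PE (18:1_14:0)
PA 36:2	PA	[M-H]-	699.4970	PA (18:1_18:1)
PE 34:2	PE	[M-H]-	714.5079	PE (16:1_18:1)
PE 36:3	PE	[M-H]-	740.5236	PE (18:1_18:2)
PS 42:5	PS	[M-H]-	864.5760	PS (22:1_20:4)/PS (22:4_20:1)
PI 40:4	PI	[M-H]-	913.5812	PI (18:0_22:4)
PI 40:3	PI	[M-H]-	915.5968	PI (18:1_22:2)/PI (18:0_22:3)
PE O-38:4	PE-O	[M-H]-	752.5599452	PE (O-18:0_20:4)/PE (O-18:1_20:3)
PS 38:3	PS	[M-H]-	812.5447452	PS (18:0_20:3)
PS 40:4	PS	[M-H]-	838.5603452	PS (18:0_22:4)
PS 44:6	PS	[M-H]-	890.5917	PS (22:4_22:2)
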