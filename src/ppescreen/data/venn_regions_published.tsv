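direction	region	count
up	S_only	190
up	E_only	373
up	C_only	633
up	SE_only	25
up	SC_only	93
up	EC_only	53
up	SEC	57
down	S_only	233
down	E_only	187
down	C_only	440
down	SE_only	18
down	SC_only	37
down	EC_only	9
down	SEC	4
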