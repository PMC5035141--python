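gene_id	source
Atoh1	hair-cell studies
Slc12a2	inner-ear studies
CyclinA1	proliferation studies
CyclinD1	proliferation studies
c-Myc	proliferation studies
Ezrin	cytoskeleton studies
Gdnf	kidney/ear studies
Sox3	placode studies
Sox2	placode studies
Sall1	kidney studies
MyoD1	myogenesis studies
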