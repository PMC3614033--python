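# Footnotes to the reference dataset.
# category=hitchhiker: the allele in `gene` is genetically linked to the causal mutation
#   in `partner` and segregated at a lower frequency; it is excluded from the main table.
# category=timezero: the allele was already present in the time-zero founder strain and
#   is excluded even though it segregated above threshold.
# category=low_final_frequency: the main-table allele was below 5% of the final evolved
#   population and is omitted from sweep time courses.
category	clone	gene	detail	partner
hitchhiker	EvoClone3	atg4		SIN4
hitchhiker	EvoClone7A	slx4	promoter	ACE2
hitchhiker	EvoClone7B	thi3		RAM1
hitchhiker	EvoClone7B	crt10		IRA2
hitchhiker	EvoClone8	crh1	promoter	UBR1
hitchhiker	EvoClone9	brr1		MED1
hitchhiker	EvoClone9	nsp1	promoter	IRC8
hitchhiker	EvoClone10	pri2	promoter	RGT1
hitchhiker	EvoClone10	ino80		NUT1
timezero	EvoClone2	ira1	F664I
timezero	EvoClone8	phm8	I97N
timezero	EvoClone8	rpl37a	-52 T->G
timezero	EvoClone8	vta1	A247V
timezero	EvoClone8	yor1	E393D
timezero	EvoClone9	vta1	A247V
timezero	EvoClone10	aim32	E241G
timezero	EvoClone10	irs4	N257S
timezero	EvoClone10	nnt1	-427 T->C
timezero	EvoClone10	prp9	N155S
timezero	EvoClone10	yrb1	N120I
low_final_frequency	EvoClone7C	puf4	Q654*
low_final_frequency	EvoClone8	mit1	W63*
low_final_frequency	EvoClone9	mcd1	S175L
low_final_frequency	EvoClone10	top3	V560A
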