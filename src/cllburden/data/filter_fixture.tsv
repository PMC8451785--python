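patient_id	gene	chrom	pos	ref	alt	depth	alt_reads	vaf	is_exonic	is_hotspot	sift_class	cadd_phred	pop_maf	in_pop_db	expected_verdict	expected_failed_rules
PA01	NOTCH1	chr9	139390648	G	A	150	8		TRUE	TRUE	tolerated	5		FALSE	retained	
PA01	ATM	chr11	108098525	C	T	100	5		TRUE	FALSE	deleterious	25		FALSE	retained	
PA02	SF3B1	chr2	198266834	T	C	250	5	0.02	TRUE	FALSE		30		FALSE	retained	
PA02	TP53	chr17	7577538	C	T	500	50	0.1	TRUE	FALSE	deleterious			FALSE	retained	
PA03	BIRC3	chr11	102207560	A	G	400	40	0.1	TRUE	FALSE	tolerated	28		FALSE	retained	
PA01	SF3B1	chr2	198269800	G	A	300	30	0.1	TRUE	TRUE				FALSE	retained	
PA03	XPO1	chr2	61719472	G	T	99	50		TRUE	FALSE	deleterious	30		FALSE	rejected	min_depth
PA04	MYD88	chr3	38182641	T	C	150	4		TRUE	FALSE	deleterious	30		FALSE	rejected	min_alt_reads
PA04	ATM	chr11	108121426	G	A	1000	15	0.015	TRUE	FALSE	deleterious	30		FALSE	rejected	min_vaf
PA05	SF3B1	chr2	198267483	A	C	80	3		TRUE	FALSE	deleterious	30		FALSE	rejected	min_depth;min_alt_reads
PA05	NOTCH1	chr9	139399400	C	G	300	30	0.1	TRUE	FALSE	deleterious	30	0.02	TRUE	rejected	polymorphism_maf
PA06	TP53	chr17	7578406	C	A	300	30	0.1	TRUE	FALSE	deleterious	30	0.01	TRUE	rejected	polymorphism_maf
PA06	ATM	chr11	108155007	A	T	300	30	0.1	TRUE	FALSE	deleterious	30	0.0005	TRUE	manual_review	manual_review
PA01	TNFAIP3	chr6	138196066	C	T	300	30	0.1	TRUE	FALSE	deleterious	30		TRUE	manual_review	manual_review
PA06	NOTCH1	chr9	139391212	A	C	300	30	0.1	TRUE	TRUE	tolerated	5	0.05	TRUE	rejected	polymorphism_maf
PA02	BIRC3	chr11	102201729	T	A	300	30	0.1	TRUE	FALSE	tolerated	5		FALSE	rejected	pathogenicity
PA03	MYD88	chr3	38182259	G	C	300	30	0.1	TRUE	FALSE	tolerated			FALSE	rejected	pathogenicity
PA04	XPO1	chr2	61718472	A	G	300	30	0.1	TRUE	FALSE				FALSE	manual_review	manual_review
PA05	TP53	chr17	7579312	G	T	300	30	0.1	FALSE	FALSE	deleterious	30		FALSE	rejected	exonic
PA02	ATM	chr11	108186610	T	G				TRUE	FALSE	deleterious	30		FALSE	manual_review	missing_quality_field
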