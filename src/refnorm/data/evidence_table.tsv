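# Curated table of published experimental set-ups assessing lithium's effect
# on BCL2 transcript/protein levels.  One row = one experimental set-up
# (a tissue x dose x duration x assay combination within a study).
# Columns: study_ref = citation number in the source review; outcome codes:
#   NS = no significant effect; sig_up / sig_down = significant change with
#   at least one significance star; direction_only = a direction reported
#   with no statistics (or n = 1).
# Rows 5 and 45 report two fold changes on one line (two doses within the
# stated range); each such line is one set-up counted once (flagged dual).
study_ref	species	tissue	dose	regimen	n	assay	normalizer	effect_size	outcome	stars	note
3	Rat	FC	4 meq/kg/day	9 days	10	WB	NA	NS	NS	0
3	Rat	FC	4 meq/kg/day	4 weeks	10	WB	NA	+2.1	sig_up	1
2	Rat	CGC	0.5-5 mM	7 days	3	NB	NA	NS	NS	0
2	Rat	CGC	0.5 mM	7 days	3	WB	NA	NS	NS	0
2	Rat	CGC	1-5 mM	7 days	3	WB	NA	+1.6/+2.5	sig_up	1	dual
30	Rat	DG	4 meq/kg/day	2 days	4	IHC	NA	NS	NS	0
30	Rat	DG	4 meq/kg/day	4 weeks	4	IHC	NA	+1.4	sig_up	1
55	Rat	RGC	0.2-5 mM	5 days	1	qPCR	Gapdh	increase	direction_only	0
31	Rat	DG	4 meq/kg/day	4 weeks	5	IHC	NA	+1.25	sig_up	2
75	Rat	RGC	30 mg/kg/day	7 days	NA	IHC	NA	increase	direction_only	0
76	Rat	DG	1 meq/kg/day	2 weeks	9	ELISA	NA	NS	NS	0
76	Rat	CA1	1 meq/kg/day	2 weeks	9	ELISA	NA	NS	NS	0
77	Rat	DG	1 meq/kg/day	4 weeks	6	ELISA	NA	+1.33	sig_up	2
77	Rat	CA1	1 meq/kg/day	4 weeks	6	ELISA	NA	+1.15	sig_up	1
20	Rat	FC	50 mg/kg/day	21 days	20	MA	NA	NS	NS	0
56	Rat	PNC	1 mM	7 days	7	qPCR	Gapdh	NS	NS	0
56	Rat	PAC	1 mM	7 days	7	qPCR	Gapdh	NS	NS	0
56	Rat	PNAC	1 mM	7 days	7	qPCR	Gapdh	NS	NS	0
56	Rat	PNC	1 mM	7 days	7	ELISA	NA	NS	NS	0
56	Rat	PAC	1 mM	7 days	7	ELISA	NA	+2.75	sig_up	1
56	Rat	PNAC	1 mM	7 days	7	ELISA	NA	NS	NS	0
78	Rat	HP	20-63 mg/kg/day	5 days	4	qPCR	Rpl24	NS	NS	0
58	Rat	FC	47 mg/kg/day	13 days	10	WB	Actb	+1.4	sig_up	2
58	Rat	HP	47 mg/kg/day	13 days	10	WB	Actb	+1.3	sig_up	2
17	Mouse	Brain	4 g/kg chow	2 weeks	10	MA	NA	NS	NS	0
18	Mouse	Brain	8 mmol/kg/day	7 days	6	qPCR	Gapdh	NS	NS	0
18	Mouse	Brain	8 mmol/kg/day	7 days	6	MA	NA	NS	NS	0
21	Mouse	HSPC	5 mM	7 days	3	MA	NA	NS	NS	0
14	Mouse	FC	2-4 g/kg chow	2 weeks	13	qPCR	Mapk6	NS	NS	0
14	Mouse	HC	2-4 g/kg chow	2 weeks	13	qPCR	Mapk6	-1.2	sig_down	1
22	Mouse	MSC	2.5 mM	24 h	4	MA	NA	NS	NS	0
22	Mouse	MSC	2.5 mM	24 h	4-6	qPCR	PPIA	NS	NS	0
35	Chick	NM	1.5-3 mM/kg	17 days	6	IHC	NA	+1.5	sig_up	1
59	Human (BP)	Blood	>300 mg	2-8 weeks	10	MA	NA	NS	NS	0
59	Human (BP)	Blood	>300 mg	2-8 weeks	10	qPCR	NA	NS	NS	0
79	Human (Manic)	Serum	900-1200 mg/day	~1 month	20	ELISA	NA	NS	NS	0	combined with additional medications
67	Cell line	hNT	0.75-2 mM	7 days	24	qPCR	18s rRNA	NS	NS	0
67	Cell line	SVG	0.75-2 mM	7 days	24	qPCR	18s rRNA	NS	NS	0
67	Cell line	SVG	0.75-2 mM	7 days	24	WB	NA	NS	NS	0
28	Cell line	PC12	2 mM	7 days	3	WB	NA	+1.2	sig_up	1
57	Cell line	SH-SY5Y	1 mM	7 days	5	WB	beta-tubulin	+1.65	sig_up	1
19	Cell line	SK-N-AS	1.5 mM	33 days	5	MA	NA	NS	NS	0
29	Cell line	SH-SY5Y	1 mM	6 h/72 h	4	MA	NA	NS	NS	0
29	Cell line	SH-SY5Y	1-2 mM	48 h	4	qPCR	NA	NS	NS	0
29	Cell line	SH-SY5Y	3-5 mM	48 h	4	qPCR	NA	+1.6/+2.2	sig_up	1	dual
80	Cell line	SH-SY5Y	1 mM	6 h	9	qPCR	18s rRNA	NS	NS	0
27	Cell line	SH-SY5Y	2 mM	12 h	5	qPCR	Gapdh	+3.5	sig_up	1
27	Cell line	SH-SY5Y	2 mM	12 h	5	WB	beta-Actin	+1.7	sig_up	1
81	C. elegans	Whole organism	10 mM	life-time	6	MA	NA	NS	NS	0
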