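family_id	female_age	gene	mode	maternal_variants	paternal_variants	cycles	total_embryos	transferable	implantation_times	pregnancies	miscarriages	live_births	outcome	note
F6711	32	SLC26A4	AR	c.1975G>C	c.1174A>T	1	17	11	2	1	0	1	Normal hearing (Twins)
F6166	32	SLC26A4	AR	c.1174A>T	c.919-2A>G	1	9	3	2	2	0	1	Normal hearing	intrauterine_death_38w
F3497	36	SLC26A4	AR	c.1229C>T	c.2168A>G	1	9	2	1	1	0	1	Normal hearing
F1884	26	GJB2	AR	c.299delAT	c.235delC	2	11	3	2	0	0	0	Withdrew	grandparent_reference
F7414	27	SLC26A4	AR	c.2168A>G	c.919-2A>G	1	5	3	1	1	0	1	Normal hearing
F8659	30	SLC26A4	AR	c.919-2A>G	c.919-2A>G	1	6	3	1	1	0	1	Normal hearing
F8085	33	SLC26A4	AR	c.919-2A>G	c.919-2A>G/c.1225C>T	1	5	2	2	2	1	1	Normal hearing
F10284	31	SLC26A4	AR	c.2168A>G	c.697G>C	1	7	0	0	0	0	0	Withdrew
F7047	32	GJB2	AR	c.257C>G	c.605ins46	1	3	1	0	0	0	0	Waiting for transfer
F2530	35	SLC26A4	AR	exon5-6del	c.919-2A>G	1	9	6	1	1	0	1	Normal hearing
F8241	32	SLC26A4	AR	c.589G>A	c.1229C>T	2	13	3	3	2	1	1	Normal hearing
F10449	32	GJB2	AR	c.235delC	c.235delC	1	6	2	2	1	0	1	Normal hearing
F12131	33	GJB2	AR	c.235delC	c.235delC	1	6	3	1	0	0	0	Waiting for transfer
F12198	31	GJB2	AR	c.512insAACG	c.109G>A/c.235delC	1	2	1	1	1	0	1	Normal hearing
F8096	40	SLC26A4	AR	c.1975G>C	c.2168A>G	1	3	1	1	1	0	1	Normal hearing
F932	37	SLC26A4	AR	c.919-2A>G	c.1975G>C	2	16	4	2	2	1	1	Normal hearing
F12244	31	SLC26A4	AR	c.754T>C	c.2168A>G	1	13	2	1	1	0	1	Normal hearing
F9323	33	GJB2	AR	c.299delAT	c.299delAT	1	7	2	1	0	0	0	Waiting for transfer
F14118	29	SLC26A4	AR	c.1586T>G	c.249G>A	1	10	3	3	1	1	0	Withdrew
M464	28	SLC26A4	AR	exon5-6del	c.919-2A>G	1	4	1	1	1	0	1	Normal hearing
F308	33	SLC26A4	AR	c.754T>C	c.2014G>A	1	10	6	1	1	0	1	Normal hearing
F12585	39	GJB2	AR	c.235delC	c.235delC	1	2	0	0	0	0	0	Withdrew
F3105	38	SLC26A4	AR	c.919-2A>G	c.919-2A>G	1	7	0	0	0	0	0	Withdrew
F6968	32	GJB2	AR	c.512insAACG	c.235delC	1	4	2	1	0	0	0	Waiting for transfer
F2242	36	SLC26A4	AR	c.919-2A>G	c.1226G>A	1	4	1	1	0	0	0	Withdrew
F7105	35	SLC26A4	AR	c.919-2A>G	c.1522A>G	1	2	1	1	0	0	0	Withdrew
F14171	38	GJB2	AR	c.235delC	c.235delC	1	6	1	1	1	0	1	Normal hearing
F10717	32	GJB2	AR	c.235delC	c.109G>A	1	8	2	1	1	0	1	Normal hearing
F11595	32	SLC26A4	AR	c.1540C>T	c.919-2A>G	1	12	4	3	1	0	1	Normal hearing
F15108	29	GJB2	AR	c.235delC	c.235delC	2	5	1	1	1	0	1	Normal hearing
F14048	28	GJB2	AR	c.299delAT(homo)	c.109G>A	1	4	1	1	1	0	1	Normal hearing
F13373	36	GJB2	AR	c.235delC	c.299delAT	2	9	3	1	1	0	1	Normal hearing
F15782	32	SLC26A4	AR	c.1373T>C	c.919-2A>G	1	3	1	1	1	0	1	Normal hearing
F11968	31	SLC26A4	AR	c.919-2A>G	c.281C>T	1	1	1	1	0	0	0	Withdrew
M759	27	GJB2	AR	c.235delC	c.176del16/c.299delAT	2	9	3	2	1	0	1	Normal hearing
F8007	38	GJB2	AR	c.235delC	c.235delC	1	6	2	2	1	0	1	Normal hearing
F15421	25	GJB2	AR	c.235delC	c.176del16/c.235delC	1	4	3	1	1	0	1	Normal hearing	grandparent_reference
F16250	29	SLC26A4	AR	c.917insG/c.919-2A>G	c.2168A>G	1	8	1	1	1	0	1	Normal hearing
F16178	27	SLC26A4	AR	c.919-2A>G	c.1286C>A	1	11	5	2	1	0	1	Normal hearing
M1318	33	SLC26A4	AR	exon1-3del	c.1174A>T	1	6	5	1	0	0	0	Normal hearing	pregnancy_outcome_inconsistent
M784	33	SLC26A4	AR	exon5-6del	c.1519delT	1	1	1	1	1	0	1	Normal hearing
F17172	33	GJB2	AR	c.235delC	c.235delC	1	4	1	1	1	0	1	Normal hearing
M855	35	SLC26A4	AR	c.439A>G	c.2168A>G	1	10	1	0	0	0	0	Waiting for transfer
M651	25	PTPN11	AD	-	c.1510A>G	1	11	3	2	1	0	1	Normal hearing
M75	35	KCNQ4	AD	c.733G>A	-	2	20	2	1	1	0	1	Normal hearing
M401	30	PAX3	AD	c.210C>A	-	1	2	2	1	1	0	1	Normal hearing
M1026	35	USH2A	AR	c.4576G>A	c.99insT	1	10	5	2	1	0	1	Normal hearing
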