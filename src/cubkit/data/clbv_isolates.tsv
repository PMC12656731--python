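# GenBank isolate screening fixture: the 10 recombinant rows carry published
# hosts and accessions; the 46 non-recombinant rows are SYNTHETIC placeholders
# (ids/accessions invented) with the documented 18 citrus / 26 Actinidia / 2 Malus partition.
id	accession	host	recombinant	major_parent	minor_parent
citrus_001	SYNNR0001	citrus	false		
citrus_002	SYNNR0002	citrus	false		
citrus_003	SYNNR0003	citrus	false		
citrus_004	SYNNR0004	citrus	false		
citrus_005	SYNNR0005	citrus	false		
citrus_006	SYNNR0006	citrus	false		
citrus_007	SYNNR0007	citrus	false		
citrus_008	SYNNR0008	citrus	false		
citrus_009	SYNNR0009	citrus	false		
citrus_010	SYNNR0010	citrus	false		
citrus_011	SYNNR0011	citrus	false		
citrus_012	SYNNR0012	citrus	false		
citrus_013	SYNNR0013	citrus	false		
citrus_014	SYNNR0014	citrus	false		
citrus_015	SYNNR0015	citrus	false		
citrus_016	SYNNR0016	citrus	false		
citrus_017	SYNNR0017	citrus	false		
citrus_018	SYNNR0018	citrus	false		
Actinidia_001	SYNNR0019	Actinidia	false		
Actinidia_002	SYNNR0020	Actinidia	false		
Actinidia_003	SYNNR0021	Actinidia	false		
Actinidia_004	SYNNR0022	Actinidia	false		
Actinidia_005	SYNNR0023	Actinidia	false		
Actinidia_006	SYNNR0024	Actinidia	false		
Actinidia_007	SYNNR0025	Actinidia	false		
Actinidia_008	SYNNR0026	Actinidia	false		
Actinidia_009	SYNNR0027	Actinidia	false		
Actinidia_010	SYNNR0028	Actinidia	false		
Actinidia_011	SYNNR0029	Actinidia	false		
Actinidia_012	SYNNR0030	Actinidia	false		
Actinidia_013	SYNNR0031	Actinidia	false		
Actinidia_014	SYNNR0032	Actinidia	false		
Actinidia_015	SYNNR0033	Actinidia	false		
Actinidia_016	SYNNR0034	Actinidia	false		
Actinidia_017	SYNNR0035	Actinidia	false		
Actinidia_018	SYNNR0036	Actinidia	false		
Actinidia_019	SYNNR0037	Actinidia	false		
Actinidia_020	SYNNR0038	Actinidia	false		
Actinidia_021	SYNNR0039	Actinidia	false		
Actinidia_022	SYNNR0040	Actinidia	false		
Actinidia_023	SYNNR0041	Actinidia	false		
Actinidia_024	SYNNR0042	Actinidia	false		
Actinidia_025	SYNNR0043	Actinidia	false		
Actinidia_026	SYNNR0044	Actinidia	false		
Malus_001	SYNNR0045	Malus	false		
Malus_002	SYNNR0046	Malus	false		
Nandina_rec_1	MT078932	Nandina	true	Malus (MW713062)	Citrus (OL871235)
Morus_rec_1	MT767171	Morus	true	Actinidia (OK513339)	Citrus (OL871235)
Actinidia_rec_1	MG604237	Actinidia	true	Actinidia (OK513347)	Actinidia (OK513324)
Prunus_rec_1	KR023647	Prunus	true	Citrus (LC758583)	Malus (MW713062)
Morus_rec_2	OP971103	Morus	true	Malus (MW713062)	Citrus (AJ318061)
Viburnum_rec_1	OP751940	Viburnum	true	Citrus (OR838782)	Actinidia (OK513336)
Malus_rec_1	MW713062	Malus	true	Actinidia (OK513339)	Citrus (OL871235)
Actinidia_rec_2	MK135436	Actinidia	true	Nandina (MT078932)	Actinidia (JN900477)
Citrus_rec_1	MH558590	citrus	true	Actinidia (OK513326)	Citrus (LC758583)
Malus_rec_2	OR855671	Malus	true	Citrus (OR838782)	Viburnum (OP751940)
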