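snp_id	gene	wgs_class	af_LES	af_SER	af_THR	q	pattern
rs422734187	OR10C1	LES-specific	0.72	0.17	0.24	1.0e-4	Significant
rs3483482816	OR1J4	LES-specific	0.58	0.40	0.37	0.084	Consistent (NS)
rs401664668	OR9A1P	LES-specific	0.75	0.26	0.20	6.0e-5	Significant
rs417884159	KRTAP16-1	LES-specific	0.60	0.22	0.25	1.7e-4	Significant
rs423335178	OR56A3	LES-specific	0.65	0.28	0.33	2.1e-4	Significant
rs408422273	OR2T1	LES-specific	0.62	0.34	0.30	3.3e-4	Significant
rs399201339	UQCRH	LES-specific	0.46	0.50	0.48	0.74	Inconsistent
rs413768160	KRTAP19-5	LES-specific	0.61	0.35	0.32	0.1	Consistent (NS)
rs161752499	ALDH4A1	LES-specific	0.56	0.43	0.38	0.11	Consistent (NS)
rs589560256	ZNF784	LES-specific	0.69	0.21	0.28	1.2e-4	Significant
11:41098506	KRTAP4-2	SER-specific	0.33	0.39	0.28	0.62	Inconsistent
rs401183126	OR13A1	SER-specific	0.23	0.73	0.21	5.8e-5	Significant
7:2388825	OR4E1	SER-specific	0.30	0.67	0.34	1.3e-4	Significant
2:229842947	SCYGR4	SER-specific	0.43	0.46	0.41	0.68	Inconsistent
rs421102706	CHD9NB	SER-specific	0.35	0.54	0.40	0.12	Consistent (NS)
rs428775201	CTXND2	SER-specific	0.32	0.50	0.37	0.14	Consistent (NS)
rs409873445	TRAV39	SER-specific	0.20	0.70	0.24	6.4e-5	Significant
rs430501547	SPZ1	SER-specific	0.28	0.65	0.36	1.8e-4	Significant
rs403620280	B3GALT9	SER-specific	0.37	0.52	0.38	0.13	Consistent (NS)
rs405518297	OR10J5	SER-specific	0.27	0.62	0.29	1.6e-4	Significant
rs410875969	OR2A12	THR-specific	0.22	0.26	0.69	6.0e-5	Significant
rs594676125	OR1J4	THR-specific	0.19	0.31	0.66	9.7e-5	Significant
13:42782435	UCN3	THR-specific	0.23	0.31	0.74	8.5e-5	Significant
rs430282808	KRTAP24-1	THR-specific	0.36	0.44	0.54	0.090	Consistent (NS)
rs419510057	TRDV3	THR-specific	0.28	0.36	0.61	3.1e-4	Significant
rs160159964	HRCT1	THR-specific	0.30	0.38	0.59	4.2e-4	Significant
12:62604417	ZNF648	THR-specific	0.26	0.30	0.63	1.8e-4	Significant
rs1087597447	RPL36AL	THR-specific	0.45	0.44	0.47	0.61	Inconsistent
rs597823465	LENEP	THR-specific	0.39	0.43	0.52	0.11	Consistent (NS)
rs430184133	KIAA0319	THR-specific	0.24	0.34	0.64	1.4e-4	Significant
rs413413850	PATJ	Common	0.41	0.52	0.46	0.32	Shared
2:526519	OR13J1	Common	0.73	0.66	0.70	0.36	Shared
rs193636766	LDLR	Common	0.19	0.27	0.22	0.41	Shared
rs405049897	OR10G6	Common	0.58	0.49	0.54	0.27	Shared
rs430446886	SLC44A4	Common	0.31	0.39	0.34	0.46	Shared
rs421315179	CDH15	Common	0.68	0.61	0.65	0.34	Shared
rs419387521	KIAA1217	Common	0.44	0.38	0.41	0.48	Shared
rs413198514	ZNF169	Common	0.24	0.36	0.29	0.44	Shared
rs595830546	KLHL33	Common	0.14	0.21	0.18	0.47	Shared
rs405666320	FAM204A	Common	0.79	0.71	0.75	0.40	Shared
rs415183610	AURKA	Common	0.48	0.56	0.51	0.45	Shared
rs412607607	TRAV39	Common	0.52	0.29	0.48	0.09	Shared
rs160646919	PRKDC	Common	0.61	0.69	0.64	0.39	Shared
rs409400253	ADAMTS3	Common	0.08	0.16	0.11	0.43	Shared
3:164283039	OR6C68	Common	0.69	0.73	0.66	0.37	Shared
rs421900588	IL17B	Common	0.54	0.63	0.57	0.38	Shared
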