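family	gene_id	locus_id	accession	function	cds_len	orf_len
Family 2	VvALDH2B4_v1	GSVIVG01007784001	XM_002283096	Mitochondrial ALDH	1617	538
Family 2	VvALDH2B4_v2	GSVIVG01007784001	JN381165	Cytosolic ALDH	1434	477
Family 2	VvALDH2B4_v3	GSVIVG01007784001	JN381166	Mitochondrial ALDH	1578	525
Family 2	VvALDH2B8	GSVIVG01020224001	XM_002263443	Mitochondrial ALDH	1617	538
Family 2	VvALDH2B9	GSVIVG01032500001	XM_002274827	Mitochondrial ALDH	1608	535
Family 3	VvALDH3F1	GSVIVG01018842001	XM_002273322	Variable substrate ALDH	1458	485
Family 3	VvALDH3H1	GSVIVG01008845001	XM_002285830	Variable substrate ALDH	1467	488
Family 3	VvALDH3H5	GSVIVG01022356001	XM_002273694	Variable substrate ALDH	1467	488
Family 3	VvALDH3J1	GSVIVG01025276001	XM_002285430	Variable substrate ALDH	1458	485
Family 5	VvALDH5F1	GSVIVG01036719001	XM_002265478	Succinic semialdehyde dehydrogenase	1593	530
Family 5	VvALDH5F2	GSVIVG01036720001	XM_002265366	Succinic semialdehyde dehydrogenase	1482	493
Family 5	VvALDH5F3	GSVIVG01036721001	XM_002265318	Succinic semialdehyde dehydrogenase	1476	491
Family 6	VvALDH6B3	GSVIVG01000336001	XM_002266354	Methylmalonate semi-aldehyde dehydrogenase	1620	539
Family 6	VvALDH6B5	GSVIVG01000338001	XM_002266580	Methylmalonate semi-aldehyde dehydrogenase	1716	571
Family 6	VvALDH6B7	GSVIVG01003951001	XM_002266343	Methylmalonate semi-aldehyde dehydrogenase	3096	1031
Family 7	VvALDH7B5	GSVIVG01015062001	XM_002278057	Antiquitin	1527	508
Family 7	VvALDH7D1	GSVIVG01016734001	XM_002272508	Antiquitin	1593	530
Family 10	VvALDH10A9	GSVIVG01007829001	XM_002283654	Betaine-aldehyde dehydrogenase	1512	503
Family 10	VvALDH10B1	GSVIVG01032588001	XM_002281948	Betaine-aldehyde dehydrogenase	1500	499
Family 11	VvALDH11A3	GSVIVG01035891001	XM_002285250	NADH-dependent glyceraldehyde-3-phosphate dehydrogenase	1491	496
Family 11	VvALDH11B1	GSVIVG01023590001	XM_002279338		1491	496
Family 12	VvALDH12A1	GSVIVG01008047001	XM_002273533	Delta-1-pyrroline-5-carboxylate dehydrogenase	1668	555
Family 18	VvALDH18B1	GSVIVG01016467001	XM_002282319	Delta-1-pyrroline-5-carboxylate synthetase	2289	762
Family 18	VvALDH18B3	GSVIVG01034097001	XM_002273220	Delta-1-pyrroline-5-carboxylate synthetase	2145	714
Family 22	VvALDH22A1	GSVIVG01035003001	XM_002277707	Novel ALDH	1782	593
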