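probeset_id	raw	fold_change	median_other	gene_symbol	compartment
1427034_at	916.2	12.3	74.5	Ace	EPT
1424758_s_at	1862.1	38.3	48.6	Acsm1	EPT
1451760_s_at	501.6	13	39.9	AI317395	EPT
1429254_at	708.2	14	49.9	Aqp11	EPT
1451681_at	692.0	22.2	31.1	BC089597	EPT
1453011_at	794.5	11	75.0	Bdh2	EPT
1416051_at	897.8	15.7	57.1	C2	EPT
1418013_at	7504.8	45	168.1	Cml1	EPT
1447112_s_at	2542.7	10	243.0	Cryl1	EPT
1417382_at	4464.5	13	344.0	Entpd5	EPT
1448470_at	3072.5	110	28.0	Fbp1	EPT
1435459_at	313.3	15	20.3	Fmo2	EPT
1424995_at	278.4	12.5	22.3	Glyctk	EPT
1416980_at	925.0	21	44.8	Mettl7b	EPT
1455099_at	1374.9	13.7	100.6	Mogat2	EPT
1432099_a_at	599.4	11	52.9	Prodh2	EPT
1426595_at	3224.5	24	131.7	Slc18a1	EPT
1417072_at	2460.4	37.1	66.4	Slc22a6	EPT
1416316_at	10454.9	118	88.3	Slc27a2	EPT
1448741_at	4187.5	95.4	43.9	Slc3a1	EPT
1422899_at	1178.6	35.8	32.9	Slc6a20b	EPT
1438183_x_at	834.2	18.5	45.2	Sord	EPT
1418916_at	10339.9	192.9	53.6	Spp2	EPT
1447800_x_at	12193.4	11	1129.0	Tcn2	EPT
1449890_at	1991.4	179	11.2	Ugt2b37	EPT
1426252_a_at	323.9	27.3	11.9	Umod	LoH
1449104_at	1387.7	31.6	43.9	Upk3a	MCD
1422567_at	720.7	14	51.9	Fam129a	MCD
1430641_at	2080.5	29.9	69.6	Gsdmc4	MCD
1439117_at	230.7	4.3	53.5	Clmn	MCD
1436099_at	328.9	3.2	101.2	AI836003	MCD
1456391_at	356.6	7.8	45.5	Tdrd5	RC
1418396_at	328.7	3.1	105.4	Gpsm3	RC
1446524_at	309.7	13.3	23.2	C230096N06	RC
1428664_at	193.0	8.9	21.6	Vip	RC
1419127_at	740.6	6.8	108.5	Npy	RV
1460616_at	1042.8	66.0	15.8	Slco4c1	UT
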