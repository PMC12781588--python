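# Synthetic emulation of a single-pass receptor feature table
# (domain intervals, disulfide-bonded cysteine pairs, ligand-contact residues).
type	name	start	end
protein	length	1	2555
egf_repeat	EGF_1	20	58
egf_repeat	EGF_2	59	97
egf_repeat	EGF_3	98	136
egf_repeat	EGF_4	137	175
egf_repeat	EGF_5	176	214
egf_repeat	EGF_6	215	253
egf_repeat	EGF_7	254	292
egf_repeat	EGF_8	293	331
egf_repeat	EGF_9	332	370
egf_repeat	EGF_10	371	409
egf_repeat	EGF_11	410	448
egf_repeat	EGF_12	449	487
egf_repeat	EGF_13	488	526
egf_repeat	EGF_14	527	565
egf_repeat	EGF_15	566	604
egf_repeat	EGF_16	605	643
egf_repeat	EGF_17	644	682
egf_repeat	EGF_18	683	721
egf_repeat	EGF_19	722	760
egf_repeat	EGF_20	761	799
egf_repeat	EGF_21	800	838
egf_repeat	EGF_22	839	877
egf_repeat	EGF_23	878	916
egf_repeat	EGF_24	917	955
egf_repeat	EGF_25	956	994
egf_repeat	EGF_26	995	1033
egf_repeat	EGF_27	1034	1072
egf_repeat	EGF_28	1073	1111
egf_repeat	EGF_29	1112	1150
egf_repeat	EGF_30	1151	1189
egf_repeat	EGF_31	1190	1228
egf_repeat	EGF_32	1229	1267
egf_repeat	EGF_33	1268	1306
egf_repeat	EGF_34	1307	1345
egf_repeat	EGF_35	1346	1384
egf_repeat	EGF_36	1385	1423
lnr	LNR	1449	1571
hd	HD	1572	1735
psen	PSEN	1736	1757
ram	RAM	1758	1896
ankyrin	ANK	1927	2082
tad	TAD	2180	2400
pest	PEST	2480	2555
ligand_site	LIG_420	420	420
ligand_site	LIG_421	421	421
ligand_site	LIG_448	448	448
ligand_site	LIG_449	449	449
ligand_site	LIG_450	450	450
ligand_site	LIG_451	451	451
ligand_site	LIG_452	452	452
ligand_site	LIG_469	469	469
disulfide_bond	SS_60_71	60	71
disulfide_bond	SS_98_109	98	109
disulfide_bond	SS_137_148	137	148
disulfide_bond	SS_195_206	195	206
disulfide_bond	SS_210_219	210	219
disulfide_bond	SS_250_261	250	261
disulfide_bond	SS_289_300	289	300
disulfide_bond	SS_323_332	323	332
disulfide_bond	SS_358_370	358	370
disulfide_bond	SS_406_417	406	417
disulfide_bond	SS_492_503	492	503
disulfide_bond	SS_540_552	540	552
disulfide_bond	SS_578_589	578	589
disulfide_bond	SS_607_618	607	618
disulfide_bond	SS_629_638	629	638
disulfide_bond	SS_675_687	675	687
disulfide_bond	SS_720_731	720	731
disulfide_bond	SS_760_771	760	771
disulfide_bond	SS_812_826	812	826
disulfide_bond	SS_854_866	854	866
disulfide_bond	SS_880_891	880	891
disulfide_bond	SS_937_949	937	949
disulfide_bond	SS_985_996	985	996
disulfide_bond	SS_1020_1031	1020	1031
disulfide_bond	SS_1060_1071	1060	1071
disulfide_bond	SS_1100_1111	1100	1111
disulfide_bond	SS_1155_1169	1155	1169
disulfide_bond	SS_1200_1211	1200	1211
disulfide_bond	SS_1240_1251	1240	1251
disulfide_bond	SS_1280_1291	1280	1291
disulfide_bond	SS_1320_1331	1320	1331
disulfide_bond	SS_1385_1397	1385	1397
disulfide_bond	SS_1410_1421	1410	1421
disulfide_bond	SS_1460_1472	1460	1472
disulfide_bond	SS_1537_1549	1537	1549
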