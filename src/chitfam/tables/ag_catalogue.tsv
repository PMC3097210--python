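species	new_name	old_name	group	accession	aa_length	has_cbd	est	locus
Ag	AgCht2	AgCht2	VII	XP_315650.4	485	-	-	chr2L:17,484,432–17,488,543
Ag	AgCht4	AgCht4	IV	XP_315351.4	477	+	+	chr2L:13,688,629–13,690,127
Ag	AgCht5-1	AgCht5	I	HQ456129	571	+	+	chr2R:21,584,333–21,587,318
Ag	AgCht5-2		I	HQ456130	412	-	+	chr2R:21,582,374–21,583,826
Ag	AgCht5-3		I	HQ456131	413	-	+	chr2R:21,578,829–21,580,211
Ag	AgCht5-4		I	HQ456132	409	-	+	chr2R:21,576,773–21,578,085
Ag	AgCht5-5	AgCht11	I	HQ456133	446	-	+	chr2R:21,573,544–21,574,884
Ag	AgCht6	AgCht6	VI		3045	+	+	chrX:3,235,497–3,246,126
Ag	AgCht7	AgCht7	III	XP_308858.4	1017	+	+	chr2L:39,004,840–39,009,056
Ag	AgCht8	AgCht8	IV	XP_316448.2	525	+	+	chr2L:31,040,019–31,041,796
Ag	AgCht9	AgCht9	IV	XP_307732.4	789	-	+	chr3L:13,859,882–13,862,726
Ag	AgCht10	AgCht10	II	XP_001238192.2	2402	+	+	chr3R:24,101,945–24,110,279
Ag	AgCht11		VIII	XP_310662.4	428	-	+	chrX:7713939–7717183
Ag	AgCht12	AgCht12	IV	XP_316142.4	382	-	-	chr2L:25,704,430–25,705,882
Ag	AgCht13	AgCht13	IV	XP_314312.4	388	-	+	chr2L:4,327,860–4,329,091
Ag	AgCht16	AgCht16	IV	XP_319801.4	354	-	+	chr3R:25,026,860–25,027,921
Ag	AgCht23		IV	XP_001688641.1	442	+	-	chr2L:13,682,087–13,683,505
Ag	AgCht24		IV	XP_316256.4	360	-	+	chr2L:27,626,337–27,627,404
Ag	AgIDGF4	AgIDGF4	V	XP_317398.3	447	-	+	chr3R:4,938,228–4,939,922
Ag	AgIDGF2		V	XP_001237925.1	439	-	+	chr3R:4,934,452–4,937,215
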