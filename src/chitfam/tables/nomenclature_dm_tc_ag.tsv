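species	old_name	new_name	accession
Dm	DmCht1
Dm	DmCht2	DmCht2	NP_477298.2
Dm	DmCht3
Dm	DmCht4	DmCht4	NP_524962.2
Dm	DmCht5	DmCht5	NP_650314.1
Dm	DmCht6	DmCht6	NP_572598.1
Dm	DmCht7	DmCht7	NP_647768.2
Dm	DmCht8	DmCht8	NP_611542.1
Dm	DmCht9	DmCht9	NP_611543.3
Dm	DmCht10	DmCht10	EAA46011.1
Dm	DmCht11	DmCht11	NP_572361.1
Dm	DmCht12	DmCht12	NP_726022.1
Dm	DmIDGF1	DmIDGF1	NP_477258.1
Dm	DmIDGF2	DmIDGF2	NP_477257.2
Dm	DmIDGF3	DmIDGF3	NP_723967.1
Dm	DmIDGF4	DmIDGF4	NP_727374.1
Dm	DmCht14	DmIDGF5	NP_611321.3
Dm	DmCht13	DmIDGF6	NP_477081.1
Tc		TcCht2	NP_001034516.3
Tc	TcCht4	TcCht4	NP_001073567.1
Tc	TcCht5	TcCht5	NP_001034524.1
Tc		TcCht6	XP_967813.1
Tc	TcCht7	TcCht7	NP_001036035.1
Tc	TcCht8	TcCht8	NP_001038094.1
Tc	TcCht9	TcCht9	NP_001038096.1
Tc	TcCht10	TcCht10	NP_001036067.1
Tc		TcCht11	XP_974461.1
Tc	TcCht12	TcCht12	XP_972802.2
Tc	TcCht13	TcCht13	NP_001036034.1
Tc	TcCht14	TcCht14	XP_973005.1
Tc	TcCht15	TcCht15	XP_973077.1
Tc	TcCht16	TcCht16	NP_001034515.1
Tc		TcCht17	XP_972719.1
Tc		TcCht18	XP_973161.2
Tc		TcCht19	XP_973119.2
Tc	TcCht2	TcCht20	XP_970191.2
Tc	TcCht6	TcCht21	NP_001034517.1
Tc	TcCht11	TcCht22	NP_001038095.1
Tc	TcIDGF2	TcIDGF2	NP_001038092.1
Tc	TcIDGF4	TcIDGF4	NP_001038091.1
Ag	AgCht2	AgCht2	XP_315650.4
Ag	AgCht4	AgCht4	XP_315351.4
Ag	AgCht5	AgCht5-1	HQ456129
Ag		AgCht5-2	HQ456130
Ag		AgCht5-3	HQ456131
Ag		AgCht5-4	HQ456132
Ag	AgCht11	AgCht5-5	HQ456133
Ag	AgCht6	AgCht6
Ag	AgCht7	AgCht7	XP_308858.4
Ag	AgCht8	AgCht8	XP_316448.2
Ag	AgCht9	AgCht9	XP_307732.4
Ag	AgCht10	AgCht10	XP_001238192.2
Ag		AgCht11	XP_310662.4
Ag	AgCht12	AgCht12	XP_316142.4
Ag	AgCht13	AgCht13	XP_314312.4
Ag	AgCht16	AgCht16	XP_319801.4
Ag		AgCht23	XP_001688641.1
Ag		AgCht24	XP_316256.4
Ag		AgIDGF2	XP_001237925.1
Ag	AgIDGF4	AgIDGF4	XP_317398.3
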