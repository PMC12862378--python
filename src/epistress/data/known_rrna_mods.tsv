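molecule	position	mod
16S	516	Y
16S	527	m7G
16S	966	m2G
16S	967	m5C
16S	1207	m2G
16S	1402	m4Cm
16S	1407	m5C
16S	1498	m3U
16S	1516	m2G
16S	1518	m62A
16S	1519	m62A
23S	745	m1G
23S	746	Y
23S	747	m5U
23S	955	Y
23S	1618	m6A
23S	1835	m2G
23S	1911	Y
23S	1915	m3Y
23S	1917	Y
23S	1939	m5U
23S	1962	m5C
23S	2030	m6A
23S	2069	m7G
23S	2251	Gm
23S	2445	m2G
23S	2449	D
23S	2457	Y
23S	2498	Cm
23S	2501	ho5C
23S	2503	m2A
23S	2504	Y
23S	2552	Um
23S	2580	Y
23S	2604	Y
23S	2605	Y
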