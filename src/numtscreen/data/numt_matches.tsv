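pair_id	symbol	chromosome	accession	source_db	position_printed	size_printed_bp	status
DM#3	⊚	11	NT_009237.18	N	10471156–10471538	383	ok
DM#3	⊚	11	AC021914.7	L	43491–43873	383	ok
DM#4	⊚	11	NT_009237.18	N	10470794–10471234	441	ok
DM#4	⊚	11	AC021914.7	L	43795–44235	441	ok
DM#4	⊚	5	NT_006713.15	N	30541284–30541724	441	ok
DM#4	⊚	5	AC022223.18	L	79289–79727	441	ok
DM#5	⊚	11	NT_009237.18	N	10470456–10470921	466	ok
DM#5	⊚	11	AC021914.7	L	44108–44573	466	ok
DM#5	⊚	3	NT_005612.16	N	2831946–2832411	466	ok
DM#5	⊚	X	AC024033.4	L	109808–110273	466	ok
DM#8	⊚	17	NT_024862.14	N	356823–357372	550	ok
DM#8	⊚	17	NT_024862.13	L	340349–340898	550	ok
DM#8	⊚	17	AF227907.1	L	5396–5945	550	ok
DM#8	⊚	17	AC107940.13	L	97187–97736	550	ok
DM#12	⊚	1	NT_004350.19	N	43365–43734	370	ok
DM#12	⊚	1	AF134583.1	L	270–639	370	ok
DM#12	⊚	6	AL359496.30	L	87935–88304	370	ok
DM#13	△	1	NT_004350.19	N	43687–44185	499	ok
DM#13	△	1	AF134583.1	L	592–1090	499	ok
DM#13	△	6	AL359496.30	L	88257–88755	499	ok
DM#15	⊚	1	NT_004350.19	N	44610–45108	499	ok
DM#15	⊚	1	AF134583.1	L	1515–2013	499	ok
DM#15	△	6	AL359496.30	L	89181–89685	499	ok
DM#16	⊚	1	NT_004350.19	N	45043–45527	485	ok
DM#16	⊚	1	AF134583.1	L	1948–2432	485	ok
DM#16	⊚	1	AF035429.1	L	58–542	485	ok
DM#17	△	1	NT_004350.19	N	45448–45851	404	ok
DM#17	△	1	AF035429.1	L	463–866	404	ok
DM#17	△	6	AL359496.30	L	90025–90428	404	ok
DM#18	⊚	1	NT_004350.19	N	45754–46014	260	ok
DM#18	⊚	1	AF134583.1	L	2659–2918	260	ok
DM#18	⊚	1	AF035429.1	L	769–1028	260	ok
DM#18	△	6	AL359496.30	L	90331–90590	260	ok
DM#19	⊚	1	NT_004350.19	N	45930–46271	342	ok
DM#19	⊚	1	AF134583.1	L	2834–3175	342	ok
DM#19	⊚	1	AF035429.1	L	944–1285	342	ok
DM#19	⊚	6	AL359496.30	L	90506–90847	342	ok
DM#20	⊚	1	NT_004350.19	N	46137–46674	538	ok
DM#20	⊚	1	AF134583.1	L	3041–3578	538	ok
DM#20	⊚	1	AF035429.1	L	1151–1688	538	ok
DM#20	⊚	6	AL359496.30	L	90713–91250	538	ok
DM#21	⊚	1	NT_004350.19	N	46586–46865	280	ok
DM#21	⊚	1	AF134583.1	L	3490–3769	280	ok
DM#21	⊚	1	AF035429.1	L	1600–1879	280	ok
DM#21	⊚	6	AL359496.30	L	9116291441	280	unparseable_position
DM#22	⊚	1	NT_004350.19	N	46795–47274	480	ok
DM#22	⊚	1	AF134583.1	L	3699–4178	480	ok
DM#22	□	6	AL359496.30	L	91371–91850	480	undefined_symbol
DM#24	□	1	NT_004350.19	N	47647–48106	460	undefined_symbol
DM#24	□	1	AF134583.1	L	4551–5010	460	undefined_symbol
DM#24	□	6	AL359496.30	L	92225–92684	460	undefined_symbol
DM#25	▾	1	NT_004350.19	N	48035–48257	223	ok
DM#25	#	1	AF134583.1	L	4939–5162	223	ok
DM#25	▾	6	AL359496.30	L	9261392835	223	unparseable_position
DM#30	▽	5	NM_001838952.21	N	39403487–39403839	356	ok
DM#30	▽	5	AC008670.6	L	8174382013	356	unparseable_position
DM#31	▴	5	NT_34772.6	N	42577624–42577823	200	ok
DM#31	▴	5	AC008670.6	L	81994–82193	200	ok
DM#33	▴	5	NT_34772.6	N	42577043–42577526	484	ok
DM#33	▴	5	AC008670.6	L	82291–82274	484	inconsistent_position
DM#34	#	5	NT_34772.6	N	42576639–42577171	533	ok
DM#34	#	5	AC021965.3	L	94060–94592	533	ok
DM#35	▴	5	NW_001838952.2	N	4525902–4526443	542	ok
DM#35	▴	5	AC008670.6	L	83113–83654	542	ok
DM#38	□	5	NW_001838952.2	N	4527054–4527559	506	undefined_symbol
DM#38	□	5	AC008670.6	L	84265–84770	506	undefined_symbol
DM#43	#	5	NT_34772.6	N	7695705–7696149	445	ok
DM#43	#	5	AC021965.3	L	97423–97867	445	ok
SB#2	▾	17	NT_024862.14	N	356087–358091	2005	ok
SB#2	▾	17	NT_024862.13	L	339613–341617	2005	ok
SB#2	▾	17	AF227907.1	L	4660–6664	2005	ok
SB#2	▾	17	AC107940.13	L	96451–98455	2005	ok
SB#5	⊚	1	NT_004350.19	N	46784–48808	2025	ok
SB#5	⊚	1	AF134583.1	L	3688–5712	2025	ok
SB#5	△	5	NT_034772.6	N	7701074–7703100	2027	ok
SB#5	△	5	AC021965.3	L	91360–93386	2027	ok
SB#5	⊚	6	AL359496.30	L	90471–92497	2027	ok
SB#6	△	5	AC021965.3	L	92381–94466	2086	ok
SB#6	▽		NT_034772.6	N			incomplete
SB#7	▽	5	AC008670.6	L	82935–85039	2106	ok
SB#7	▽	5	NT_034772.6	N	42572871–42574867	1997	ok
SB#8	▽	5	AC008670.6	L	84950–86946	1997	ok
SB#10	▾	8	NT_167187.1	N	20727551–20729527	1977	ok
SB#10	▾	8	NT_007995.8	L	190554–192530	1977	ok
SB#10	▾	X	AL158819.14	L	2580–4588	2007	ok
SB#12	▽	1	NT_004350.19	N	44137–46231	2095	ok
SB#12	▽	1	NW_001838563.2	N	2027–4120	2095	ok
SB#12	▽	1	AF134583.1	L	1042–3135	2095	ok
SB#12	▽	6	AL359496.30	L	88711–90807	2097	ok
SB#13	⊚	1	NT_004350.19	N	46166–48208	2043	ok
SB#13	▽	1	NW_001838563.2	N	5–−2092	2043	unparseable_position
SB#13	⊚	1	AF134583.1	L	3070–5112	2043	ok
SB#13	⊚	6	AL359496.30	L	90742–92786	2045	ok
SB#15	▾	5	NT_034772.6	N	7697929–7700008	2080	ok
SB#15	▾	5	AC021965.3	L	93563–95642	2080	ok
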