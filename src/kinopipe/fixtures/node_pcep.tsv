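peptide_id	protein_name	phosphosite	uniprot_accession	fold_change	p_value	direction
p47phox_S370	p47phox	S370	P14598	1.71	0.003	INCREASED
NFAT3_S676	NFAT3	S676	Q14934	1.69	0.009	INCREASED
P27kip1_T157	P27kip1	T157	P46527	1.64	0.004	INCREASED
SHC3_Y341	SHC3	Y341	Q92529	1.62	0.004	INCREASED
K8_S74	K8	S74	P05787	1.58	0.02	INCREASED
STAT1_S708	STAT1	S708	P42224	1.57	0.006	INCREASED
Mek2_S226	Mek2	S226	P36507	1.57	0.04	INCREASED
IKK-alpha_S473	IKK-alpha	S473	O15111	1.55	0.02	INCREASED
Rack1_Y194	Rack1	Y194	P63244	1.52	0.0004	INCREASED
CHOP_S79	CHOP	S79	P35638	1.51	0.02	INCREASED
STAT1_S727	STAT1	S727	P42224	1.49	0.02	INCREASED
MK2_Y415	MK2	Y415	P16389	1.48	0.01	INCREASED
Rab5A_S123	Rab5A	S123	P20339	1.47	0.01	INCREASED
DVL1_S679	DVL1	S679	O14640	1.46	0.0002	INCREASED
PI3K p85 b_Y464	PI3K p85 b	Y464	O00459	1.46	0.05	INCREASED
ACC1_S80	ACC1	S80	Q13085	1.45	0.02	INCREASED
Smad6_S435	Smad6	S435	O43541	1.41	0.02	INCREASED
EP300_S2366	EP300	S2366	Q09472	1.4	0.007	INCREASED
4E-BP1_T46	4E-BP1	T46	Q13541	1.39	0.04	INCREASED
Flt3_Y842	Flt3	Y842	P36888	1.37	0.05	INCREASED
Rab5A_Y205	Rab5A	Y205	P20339	1.36	0.01	INCREASED
IRAK4_T208	IRAK4	T208	P51617	1.34	0.01	INCREASED
Crk_Y221	Crk	Y221	P46108	1.34	0.04	INCREASED
IFNGR1_S495	IFNGR1	S495	P15260	1.33	0.006	INCREASED
Grb10_S150	Grb10	S150	Q13322	1.33	0.02	INCREASED
Cdc42_Y64	Cdc42	Y64	P60953	1.32	0.02	INCREASED
Met_Y1003	Met	Y1003	P08581	1.32	0.02	INCREASED
TGFBR1_T204	TGFBR1	T204	P36897	1.31	0.03	INCREASED
Sek1_S80	Sek1	S80	P45985	1.3	0.02	INCREASED
CTNNB1_Y654	CTNNB1	Y654	P35222	1.3	0.05	INCREASED
Calmodulin_Y99	Calmodulin	Y99	P62158	1.27	0.03	INCREASED
Cdc2_T161	Cdc2	T161	P06493	1.27	0.05	INCREASED
BRAF1_S579	BRAF1	S579	P15056	1.26	0.02	INCREASED
IKK-alpha_T23	IKK-alpha	T23	O15111	1.25	0.02	INCREASED
Cdk4_S150	Cdk4	S150	P11802	1.25	0.02	INCREASED
NFkB-p65_S276	NFkB-p65	S276	Q04206	1.24	0.01	INCREASED
Rab4_Y189	Rab4	Y189	P20338	1.24	0.03	INCREASED
Rack1_Y52	Rack1	Y52	P63244	1.21	0.03	INCREASED
TBK1_S172	TBK1	S172	Q9UHD2	1.2	0.02	INCREASED
TrKA_Y680	TrKA	Y680	P04629	1.19	0.04	INCREASED
Grb2_Y37	Grb2	Y37	P62993	1.18	0.02	INCREASED
caveolin-1_Y6	caveolin-1	Y6	Q03135	1.18	0.03	INCREASED
Shc1_Y349	Shc1	Y349	P29353	1.18	0.03	INCREASED
TRAF6_Y353	TRAF6	Y353	Q9Y4K3	1.18	0.03	INCREASED
EGFR_T693	EGFR	T693	P00533	1.16	0.03	INCREASED
PI3Kp85 B_Y605	PI3Kp85 B	Y605	O00459	1.16	0.04	INCREASED
PAK4_S474	PAK4	S474	O96013	1.16	0.04	INCREASED
p38 delta_Y182	p38 delta	Y182	O15264	1.15	0.01	INCREASED
IRAK4_T235	IRAK4	T235	P51617	1.15	0.03	INCREASED
gp130_Y676	gp130	Y676	P40189	1.15	0.04	INCREASED
Kit_Y568	Kit	Y568	P10721	1.15	0.05	INCREASED
MEK1_S297	MEK1	S297	Q02750	1.14	0.03	INCREASED
4E-BP1_S64	4E-BP1	S64	Q13541	1.1	0.004	INCREASED
Mlk3_T277	Mlk3	T277	Q16584	1.1	0.03	INCREASED
PTEN_Y315	PTEN	Y315	P60484	1.1	0.04	INCREASED
TAK1_T187	TAK1	T187	O43318	1.03	0.04	INCREASED
PKACa_S10	PKACa	S10	P17612	-1.74	0.03	DECREASED
P300_S89	P300	S89	Q09472	-1.61	0.007	DECREASED
PKACa_S338	PKACa	S338	P17612	-1.54	0.04	DECREASED
IKK-beta_Y188	IKK-beta	Y188	O14920	-1.54	0.03	DECREASED
Lyn_Y396	Lyn	Y396	P07948	-1.53	0.01	DECREASED
p70S6K_S447	p70S6K	S447	P23443	-1.5	0.02	DECREASED
MyD88_Y257	MyD88	Y257	Q99836	-1.49	0.04	DECREASED
Jak2_Y813	Jak2	Y813	O60674	-1.48	0.02	DECREASED
PKACa_T197	PKACa	T197	P17612	-1.46	0.005	DECREASED
p67phox_S208	p67phox	S208	P19878	-1.46	0.0008	DECREASED
MSK2_S360	MSK2	S360	O75676	-1.43	0.01	DECREASED
IKK-a_S180	IKK-a	S180	O15111	-1.42	0.02	DECREASED
Lyn_Y507	Lyn	Y507	P07948	-1.42	0.02	DECREASED
PPARG_S112	PPARG	S112	P37231	-1.41	0.04	DECREASED
Jak2_Y119	Jak2	Y119	O60674	-1.41	0.04	DECREASED
Mnk1_T250	Mnk1	T250	Q9BUB5	-1.41	0.03	DECREASED
p67phox_T233	p67phox	T233	P19878	-1.41	0.01	DECREASED
MAPK14_T179	MAPK14	T179	Q16539	-1.41	0.007	DECREASED
PPP2CA_T304	PPP2CA	T304	P67775	-1.4	0.05	DECREASED
Pyk2_S213	Pyk2	S213	Q14289	-1.38	0.01	DECREASED
Mnk1_T255	Mnk1	T255	Q9BUB5	-1.37	0.008	DECREASED
NFAT1_S326	NFAT1	S326	Q13469	-1.36	0.01	DECREASED
STMN1_S15	STMN1	S15	P16949	-1.34	0.02	DECREASED
NFAT1_S110	NFAT1	S110	Q13469	-1.32	0.01	DECREASED
IL4R_Y713	IL4R	Y713	P24394	-1.32	0.01	DECREASED
MEK1_T385	MEK1	T385	Q02750	-1.31	0.04	DECREASED
STAT5B_S731	STAT5B	S731	P51692	-1.3	0.01	DECREASED
IKK-g_S43	IKK-g	S43	Q9Y6K9	-1.29	0.03	DECREASED
SMAD3_S416	SMAD3	S416	Q15796	-1.28	0.01	DECREASED
Tgfbr2_S409	Tgfbr2	S409	P37173	-1.27	0.005	DECREASED
Keap1_S293	Keap1	S293	Q14145	-1.26	0.03	DECREASED
STAT4_S722	STAT4	S722	Q14765	-1.25	0.05	DECREASED
Jun_S63	Jun	S63	P05412	-1.25	0.04	DECREASED
PIK3R1_Y528	PIK3R1	Y528	P27986	-1.2	0.05	DECREASED
PDGFRb_Y686	PDGFRb	Y686	P09619	-1.2	0.004	DECREASED
PDK1_Y376	PDK1	Y376	O15530	-1.19	0.05	DECREASED
Pyk2_S399	Pyk2	S399	Q14289	-1.19	0.05	DECREASED
PDGFRb_Y740	PDGFRb	Y740	P09619	-1.17	0.004	DECREASED
Jak1_Y220	Jak1	Y220	P23458	-1.16	0.04	DECREASED
PDK1_S241	PDK1	S241	O15530	-1.15	0.02	DECREASED
MAPK14_T122	MAPK14	T122	Q16539	-1.14	0.04	DECREASED
TAB1_S423	TAB1	S423	Q15750	-1.12	0.05	DECREASED
ACC1_S1263	ACC1	S1263	Q13085	-1.11	0.04	DECREASED
Rab4_S199	Rab4	S199	P20338	-1.06	0.03	DECREASED
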