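peptide_id	protein_name	phosphosite	uniprot_accession	fold_change	p_value	direction
Shc1_Y439	Shc1	Y439	P29353	1.59	0.02	INCREASED
PLCG2_Y759	PLCG2	Y759	P16885	1.49	0.05	INCREASED
Smad3_S423	Smad3	S423	P84022	1.47	0.03	INCREASED
Syk_Y352	Syk	Y352	P43405	1.44	0.01	INCREASED
Syk_Y525	Syk	Y525	P43405	1.43	0.01	INCREASED
Ck2-B_S228	Ck2-B	S228	Q5SRQ6	1.35	0.04	INCREASED
Cdk4_S150	Cdk4	S150	P11802	1.34	0.02	INCREASED
p300_S2279	p300	S2279	Q09472	1.34	0.05	INCREASED
EP300_S2366	EP300	S2366	Q09472	1.33	0.0001	INCREASED
CTNNB1_Y654	CTNNB1	Y654	P35222	1.31	0.005	INCREASED
TAK1_T178	TAK1	T178	O43318	1.3	0.02	INCREASED
SEK1_T261	SEK1	T261	P45985	1.3	0.04	INCREASED
TAK1_T187	TAK1	T187	O43318	1.29	0.04	INCREASED
Grb10_S150	Grb10	S150	Q13322	1.28	0.01	INCREASED
K8_S74	K8	S74	P05787	1.27	0.02	INCREASED
Sek1_S80	Sek1	S80	P45985	1.27	0.03	INCREASED
EGFR_T693	EGFR	T693	P00533	1.26	0.007	INCREASED
SOC3_Y221	SOC3	Y221	O14543	1.26	0.02	INCREASED
TBK1_S172	TBK1	S172	Q9UHD2	1.25	0.02	INCREASED
Smad6_S435	Smad6	S435	O43541	1.24	0.02	INCREASED
Cdc42_Y32	Cdc42	Y32	P60953	1.24	0.03	INCREASED
XIAP_S87	XIAP	S87	P98170	1.23	0.02	INCREASED
IRAK4_T208	IRAK4	T208	P51617	1.21	0.01	INCREASED
SMAD3_S204	SMAD3	S204	Q15796	1.21	0.03	INCREASED
STMN1_S24	STMN1	S24	P16949	1.21	0.05	INCREASED
CDK2_Y14	CDK2	Y14	P24941	1.2	0.006	INCREASED
TrKA_Y496	TrKA	Y496	P04629	1.2	0.02	INCREASED
P27kip1_Y74	P27kip1	Y74	P46527	1.2	0.03	INCREASED
Crk_Y221	Crk	Y221	P46108	1.19	0.02	INCREASED
IRAK1_T387	IRAK1	T387	P51617	1.18	0.01	INCREASED
TNIK_T181	TNIK	T181	Q9UKE5	1.18	0.02	INCREASED
Tyk2_Y1054	Tyk2	Y1054	P29597	1.18	0.03	INCREASED
EGFR_Y869	EGFR	Y869	P00533	1.18	0.05	INCREASED
TrKA_Y757	TrKA	Y757	P04629	1.17	0.008	INCREASED
gp130_Y767	gp130	Y767	P40189	1.17	0.02	INCREASED
CREB_S117	CREB	S117	P16220	1.17	0.02	INCREASED
SHC3_Y341	SHC3	Y341	Q92529	1.17	0.03	INCREASED
PI3K p85_Y605	PI3K p85	Y605	O00459	1.17	0.05	INCREASED
Smad3_T179	Smad3	T179	P84022	1.17	0.05	INCREASED
IFNAR1_Y466	IFNAR1	Y466	P17181	1.15	0.03	INCREASED
STAT6_Y641	STAT6	Y641	P42226	1.14	0.03	INCREASED
HSP60_S70	HSP60	S70	P10809	1.14	0.03	INCREASED
GIT2_Y592	GIT2	Y592	Q14161	1.13	0.01	INCREASED
STMN1_S37	STMN1	S37	P16949	1.12	0.03	INCREASED
IFNGR1_S495	IFNGR1	S495	P15260	1.11	0.02	INCREASED
SOC3_Y204	SOC3	Y204	O14543	1.09	0.003	INCREASED
CTNNB1_S33	CTNNB1	S33	P35222	1.07	0.02	INCREASED
Lyn_Y396	Lyn	Y396	P07948	-1.5	0.05	DECREASED
IRF-3_S402	IRF-3	S402	Q14653	-1.37	0.04	DECREASED
IKK-g_S43	IKK-g	S43	Q9Y6K9	-1.35	0.01	DECREASED
IKK-b_Y188	IKK-b	Y188	O14920	-1.3	0.03	DECREASED
MDM2_S166	MDM2	S166	Q00987	-1.3	0.004	DECREASED
ACTA1_Y55	ACTA1	Y55	P68133	-1.29	0.02	DECREASED
MAVS_S233	MAVS	S233	Q7Z434	-1.28	0.04	DECREASED
Keap1_S293	Keap1	S293	Q14145	-1.28	0.02	DECREASED
MK2_Y132	MK2	Y132	P16389	-1.27	0.05	DECREASED
IKK-a_S180	IKK-a	S180	O15111	-1.26	0.0002	DECREASED
p38-a_Y322	p38-a	Y322	Q16539	-1.25	0.04	DECREASED
IRAK1_T100	IRAK1	T100	P51617	-1.25	0.02	DECREASED
IL7R_Y449	IL7R	Y449	P16871	-1.25	0.004	DECREASED
PDK1_S241	PDK1	S241	O15530	-1.24	0.001	DECREASED
Fos_S362	Fos	S362	P01100	-1.23	0.05	DECREASED
MEK1_Y385	MEK1	Y385	Q02750	-1.23	0.03	DECREASED
CREB_S133	CREB	S133	P16220	-1.23	0.02	DECREASED
Jun_S63	Jun	S63	P05412	-1.22	0.05	DECREASED
HSP70_Y525	HSP70	Y525	P08107	-1.22	0.04	DECREASED
Met_Y1003	Met	Y1003	P08581	-1.22	0.01	DECREASED
ACC1_S29	ACC1	S29	Q13085	-1.22	0.004	DECREASED
Akt1_T308	Akt1	T308	P31749	-1.21	0.05	DECREASED
JNK2_T183	JNK2	T183	P45984	-1.2	0.03	DECREASED
PDK1_Y373	PDK1	Y373	O15530	-1.2	0.01	DECREASED
Casp3_S150	Casp3	S150	P42574	-1.19	0.05	DECREASED
Mapk14_T122	Mapk14	T122	Q16539	-1.19	0.03	DECREASED
Aura_T287	Aura	T287	O14965	-1.18	0.04	DECREASED
JNK1_T183	JNK1	T183	P45983	-1.18	0.02	DECREASED
Bim_S69	Bim	S69	O43521	-1.17	0.02	DECREASED
p70S6K_S447	p70S6K	S447	P23443	-1.16	0.005	DECREASED
Mnk1_T255	Mnk1	T255	Q9BUB5	-1.15	0.05	DECREASED
CHOP_S79	CHOP	S79	P35638	-1.15	0.05	DECREASED
Mek1_S217	Mek1	S217	Q02750	-1.15	0.02	DECREASED
CDK2_T160	CDK2	T160	P24941	-1.15	0.02	DECREASED
MSK2_S360	MSK2	S360	O75676	-1.14	0.02	DECREASED
NFkB p65_S536	NFkB p65	S536	Q04206	-1.14	0.01	DECREASED
CREB_S111	CREB	S111	P16220	-1.13	0.05	DECREASED
Fyn_Y420	Fyn	Y420	P06241	-1.13	0.02	DECREASED
Met_Y1234	Met	Y1234	P08581	-1.11	0.02	DECREASED
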