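peptide_id	protein_name	phosphosite	uniprot_accession	fold_change	p_value	direction
ACC1_S29	ACC1	S29	Q13085	1.07	0.0007	INCREASED
SHC3_Y341	SHC3	Y341	Q92529	-1.19	0.04	DECREASED
NFkB-p65_S536	NFkB-p65	S536	Q04206	-1.17	0.02	DECREASED
NFAT3_S676	NFAT3	S676	Q14934	-1.16	0.02	DECREASED
IKK-alpha_S180	IKK-alpha	S180	O15111	-1.15	0.02	DECREASED
TAK1_S192	TAK1	S192	O43318	-1.1	0.04	DECREASED
P27kip1_T1576	P27kip1	T1576	P46527	-1.08	0.01	DECREASED
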