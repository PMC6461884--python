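tumour	gene	accession	mutation_type	nt_change	aa_change	gcnis	histology	meta
T1382	EIF5B	NM_015904	Missense	c.541 A > C	p.N181H		1/1	7/7
T1382	TTN	NM_003319	Missense	c.5558 T > A	p.I1853N		2/2	5/8
T1382	LPCAT1	NM_024830	Missense	c.1129 G > A	p.E377K		2/2	7/7
T1382	LPCAT1	NM_024830	Missense	c.517 G > C	p.V173L		2/2	8/8
T1382	CHRNA2	NM_000742	Missense	c.688 G > A	p.E230K		2/2	1/8
T1382	KAT6A	NM_006766	Missense	c.158 T > C	p.L53S		2/2	4/4
T1382	SYT7	NM_001252065	Missense	c.655 G > A	p.G219S		1/1	n.d.
T1382	BICD1	NM_001003398	Missense	c.490 C > T	p.R164W		2/2	1/8
T1382	FREM2	NM_207361	Missense	c.7882 C > T	p.R2628W		2/2	5/6
T1382	POLR3K	NM_016310	Stopgain	c.49 G > T	p.G17X		2/2	8/8
T1382	SNX20	NM_182854	Missense	c.911 T > A	p.I304N		2/2	8/8
T1382	SETD6	NM_024860	Missense	c.1318 A > G	p.I440V		2/2	0/6
T1382	CA5A	NM_001739	Missense	c.721 G > A	p.E241K		2/2	8/8
T1382	BRCA1	NM_007300	Missense	c.745 A > G	p.T249A		2/2	4/7
T1382	TMEM147	NM_032635	Missense	c.104 G > A	p.C35Y		2/2	1/1
T1382	SLCO4A1	NM_016354	Missense	c.175 C > T	p.L59F		2/2	8/8
T3209	MTOR	NM_004958	Missense	c.3011 G > C	p.C1004S	0/1	13/13
T3209	NRXN1	NM_001135659	Missense	c.634 G > T	p.G212C	n.d.	6/6
T3209	TAF7	NM_005642	Nonfrs del	c.738_740del	p.I247del
T3209	PDLIM7	NM_005451	Missense	c.422 C > T	p.P141L	n.d.	11/12
T3209	CCKBR	NM_176875	Missense	c.1240 C > G	p.R414G	n.d.	2/9
T3209	RNF219	NM_024546	Missense	c.1940A > T	p.Q647L	n.d.	5/5
T3209	GCOM1	NM_001285900	Missense	c.1027 G > C	p.E343Q	0/1	3/13
T3209	ABCC3	NM_003786	Acceptor	c.2415-5 C > T	Unknown	0/1	13/13
T3209	ZNFX1	NM_021035	Frs del	c.3592_3593del	p.S1198AfsX71
T3209	SHOX	NM_006883	Missense	c.310 G > A	p.V104M	n.d.	8/8
T6107	CPSF3	NM_016207	Missense	c.762 T > G	p.D254E	0/2	6/6	0/1
T6107	UACA	NM_018003	Missense	c.2272 G > C	p.D758H	n.d.	3/3	0/1
T6107	DNAJB1	NM_006145	Missense	c.200 A > G	p.Y67C
T618	CROCC	NM_014675	Nonfrs sub	c.244_246	p.Q82del	3/3
T618	ARHGEF10L	NM_018125	Acceptor	c.-43-3C > T	Unknown	0/3
T618	MYOM3	NM_152372	Nonfrs sub	c.3688_3689delinsAG	p.Q1230R	0/3
T618	TTF2	NM_003594	Missense	c.634 C > A	p.H212N	0/1
T618	KIAA0226	NM_014687	Missense	c.1963C > T	p.H655Y	3/3
T618	SMARCAD1	NM_001254949	Missense	c.226 A > G	p.N76D
T618	ASAP1	NM_001247996	Missense	c.933 G > C	p.Q311H	0/2
T618	DNAJB5	NM_001135005	Frs sub	c.1077_1093G	p.Nfs??	0/3
T618	ZDHHC6	NM_022494	Missense	c.950 G > A	p.R317H
T618	CLCF1	NM_001166212	Missense	c.468 A > T	p.E156D	0/3
T618	NDUFV1	NM_007103	Acceptor	c.511-4 G > A	Unknown	1/2
T618	LRRC10	NM_201550	Missense	c.125 G > A	p.R42H	0/3
T618	PIAS1	NM_016166	Missense	c.1712A > C	p.D571A	0/3
T618	KEAP1	NM_203500	Missense	c.610 C > T	p.R204W	3/3
T618	CSRP2BP	NM_020536	Stopgain	c.412 G > T	p.E138X	1/2
T618	CSE1L	NM_001316	Donor	c.1619 + 4 A > T	Unknown	3/3
T618	APOL3	NM_145640	Missense	c.1066 C > G	p.L356V	0/3
T618	CFP	NM_002621	Missense	c.1285 G > T	p.V429L	3/3
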