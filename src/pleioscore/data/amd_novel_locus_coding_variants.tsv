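variant_id	top_variant	chrom	pos	r2_to_top	frequency	gene	consequence	phenotype	locus_name
rs6683902	rs7523273	1	207881557	0.545	0.563	CR1L	p.I455V	SCZ	CD46/CR1L
rs2796257	rs7523273	1	207890866	0.549	0.434	CR1L	p.L491P	SCZ	CD46/CR1L
rs1550094	rs1550094	2	233385396	1.000	0.310	PRSS56	p.A30T	MYP	PRSS56
rs9860801	rs9844666	3	136088038	0.547	0.302	STAG1	p.F403F	HGT	STAG1
rs1052620	rs9844666	3	136574521	0.956	0.189	SLC35G2	p.L407L	HGT	STAG1
rs1422795	rs2277027	5	156936364	0.996	0.357	ADAM19	p.S17G	LGF	ADAM19
rs943037	rs11191548	10	104835919	0.988	0.088	CNNM2	p.A770A	BP	NT5C2
rs584961	rs634552	11	75277628	0.625	0.888	SERPINH1	p.L78L	HGT	SERPINH1
rs12811109	rs11830103	12	123471094	0.838	0.216	PITPNM2	p.H1205H	HGT	SBNO1
rs1051431	rs11830103	12	123645803	0.878	0.768	MPHOSPH9	p.Y935H	HGT	SBNO1
rs6488868	rs11830103	12	123799974	0.756	0.722	SBNO1	p.G1022G	HGT	SBNO1
rs1060105	rs11830103	12	123806219	0.988	0.223	SBNO1	p.S729N	HGT	SBNO1
rs61388686	rs11830103	12	123810873	0.591	0.664	SBNO1	p.I567I	HGT	SBNO1
rs12322888	rs11830103	12	123825559	1.000	0.225	SBNO1	p.K209K	HGT	SBNO1
rs1254319	rs10483727	14	60903757	0.613	0.301	C14orf39	p.L524F	ODCA	SIX6
rs33912345	rs10483727	14	60976537	0.978	0.597	SIX6	p.H141N	ODCA	SIX6
rs117068593	rs11627032	14	93118229	0.565	0.187	RIN3	p.R279C	BRC	RIN3
rs2470890	rs1378942	15	75047426	0.843	0.596	CYP1A2	p.N516N	BP	CSK
rs4886615	rs1378942	15	75131661	0.553	0.691	ULK3	p.A302A	BP	CSK
rs907092	rs2290400	17	37922259	0.761	0.473	IKZF3	p.S399S	T1D	GSDMB
rs11557466	rs2290400	17	38024626	0.792	0.472	ZPBP2	p.L7L	T1D	GSDMB
rs11557467	rs2290400	17	38028634	0.924	0.508	ZPBP2	p.S55I	T1D	GSDMB
rs10852935	rs2290400	17	38031674	0.792	0.472	ZPBP2	p.C174C	T1D	GSDMB
rs2305480	rs2290400	17	38062196	0.815	0.466	GSDMB	p.P302S	T1D	GSDMB
rs2305479	rs2290400	17	38062217	0.948	0.502	GSDMB	p.G295R	T1D	GSDMB
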