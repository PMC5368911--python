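variant_id	chrom	pos	phenotype	locus_name	boundary_start_mbp	boundary_end_mbp	effect_allele	published_effect	amd_or	amd_ci95	p_raw	p_adj	q_raw	q_adj	freq_controls	freq_cases	imputation_quality
rs7523273	1	207977083	SCZ	CD46/CR1L	207.8	208.1	A	1.063 (OR)	1.078	1.042-1.116	1.37E-05	2.51E-05	0.0009	5.91E-05	0.667	0.681	0.972
rs1550094	2	233385396	MYP	PRSS56	233.3	233.5	G	1.087 (HR)	1.067	1.030-1.106	0.0003	0.0019	0.0093	0.0021	0.290	0.304	0.867
rs9844666	3	135974216	HGT	STAG1	135.5	136.9	G	1.024 (SL)	1.079	1.039-1.120	6.70E-05	0.0002	0.0029	0.0003	0.753	0.768	0.999
rs7432375	3	136288405	SCZ	STAG1	135.5	136.9	G	1.073 (OR)	0.942	0.911-0.973	0.0003	0.0004	0.0095	0.0005	0.605	0.593	0.999
rs13091182	3	141133960	MYP	ZBTB38	141.0	141.3	G	1.064 (OR)	0.929	0.898-0.960	1.65E-05	5.65E-06	0.0010	2.26E-05	0.668	0.651	0.996
rs3774959	4	103511114	UC	NFKB1	103.3	103.6	A	1.119 (OR)	0.928	0.898-0.959	1.11E-05	4.44E-07	0.0007	7.71E-06	0.357	0.341	0.964
rs2277027	5	156932376	LGF	ADAM19	156.8	157.1	A	1.462 (SL)	1.096	1.059-1.133	1.31E-07	2.75E-06	1.50E-05	1.28E-05	0.651	0.667	1.000
rs2814982	6	34546560	TC	C6ORF106	34.4	34.9	C	1.045 (SL)	1.118	1.061-1.178	2.67E-05	4.82E-05	0.0014	0.0001	0.889	0.898	0.980
rs2207139	6	50845490	BMI	TFAP2B	50.7	51.0	G	1.046 (SL)	0.921	0.883-0.961	0.0001	0.0004	0.0058	0.0006	0.179	0.165	0.997
rs11776767	8	10683929	TG	PINX1	10.5	10.8	C	1.022 (OR)	0.936	0.905-0.967	8.83E-05	0.0089	0.0037	0.0089	0.380	0.370	0.999
rs3217992	9	22003223	CAD	CDKN2B	21.9	22.2	T	1.160 (OR)	0.914	0.884-0.945	1.07E-07	1.18E-05	1.35E-05	3.67E-05	0.394	0.375	1.000
rs7865618	9	22031005	ODCA;VCDR	CDKN2B	21.9	22.2	A	1.023 (SL)	0.937	0.907-0.968	9.23E-05	6.12E-05	0.0037	0.0001	0.593	0.579	1.000
rs7866783	9	22056359	POAG	CDKN2B	21.9	22.2	G	1.451 (OR)	0.936	0.906-0.967	6.67E-05	2.53E-05	0.0029	5.91E-05	0.594	0.579	0.995
rs11191548	10	104846178	BP	NT5C2	104.4	105.2	T	2.989 (SL)	0.902	0.853-0.954	0.0003	0.0012	0.0092	0.0014	0.914	0.906	1.000
rs11191560	10	104869038	BMI	NT5C2	104.4	105.2	C	1.031 (SL)	1.110	1.049-1.173	0.0003	0.0012	0.0087	0.0014	0.086	0.094	0.996
rs634552	11	75282052	HGT	SERPINH1	75.2	75.4	T	1.040 (SL)	1.120	1.069-1.173	2.08E-06	1.47E-05	0.0002	4.11E-05	0.130	0.144	0.999
rs11830103	12	123823546	HGT	SBNO1	123.3	124.0	G	1.036 (SL)	1.082	1.040-1.125	9.13E-05	0.0028	0.0037	0.0029	0.205	0.216	1.000
rs4901977	14	60789176	VCDR	SIX6	60.7	61.3	T	1.011 (SL)	0.927	0.895-0.959	1.56E-05	8.40E-06	0.0010	2.94E-05	0.319	0.306	0.996
rs2093210	14	60957279	HGT	SIX6	60.7	61.3	C	1.033 (SL)	0.920	0.890-0.950	5.00E-07	1.37E-06	4.34E-05	7.71E-06	0.417	0.401	0.997
rs33912345	14	60976537	POAG	SIX6	60.7	61.3	C	1.320 (OR)	0.919	0.889-0.949	3.51E-07	1.19E-06	3.21E-05	7.71E-06	0.413	0.397	1.000
rs10483727	14	61072875	ODCA	SIX6	60.7	61.3	T	1.026 (SL)	0.915	0.886-0.946	1.11E-07	1.06E-06	1.35E-05	7.71E-06	0.414	0.396	0.999
rs1555399	14	67984370	PD	PLEKHH1	67.9	68.1	T	1.115 (OR)	0.929	0.899-0.959	6.27E-06	0.0002	0.0004	0.0003	0.517	0.502	0.997
rs11627032	14	93104072	BRC	RIN3	93.0	93.2	T	1.060 (OR)	1.070	1.032-1.109	0.0002	0.0014	0.0086	0.0015	0.728	0.739	0.931
rs1378942	15	75077367	BP	CSK	74.9	75.3	C	1.846 (SL)	0.918	0.887-0.950	8.52E-07	1.38E-06	7.06E-05	7.71E-06	0.345	0.328	1.000
rs2290400	17	38066240	T1D	GSDMB	37.8	38.2	C	1.080 (OR)	1.068	1.034-1.103	5.47E-05	7.29E-05	0.0026	0.0001	0.494	0.508	1.000
rs9303280	17	38074031	ALG	GSDMB	37.8	38.2	C	1.070 (SL)	0.941	0.911-0.971	0.0002	0.0001	0.0068	0.0002	0.510	0.497	0.984
rs386000	19	54792761	HDL	LILRA3	54.7	54.9	C	1.049 (SL)	1.096	1.053-1.141	6.24E-06	0.0006	0.0004	0.0008	0.199	0.211	0.782
rs1547014	22	29100711	VCDR	CHEK	28.5	29.2	C	1.013 (SL)	0.936	0.904-0.969	0.0002	6.78E-05	0.0068	0.0001	0.708	0.695	0.999
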