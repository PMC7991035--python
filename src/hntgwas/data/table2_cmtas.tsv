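trait	locus_id	experiment	treatment	snp_name	chrom	pos	p_value	alleles	allelic_effect	favorable_allele	n_genes
YPP	Q1	E1	CNT	Chr1pos6542949.1	1	6542949	8E-05	G:A	5.92	A	16
YPP	Q2	E1	CNT	Chr2pos31467953.1	2	31467953	5E-05	G:A	-3.24	G	14
YPP	Q3	E2	CNT	Chr2pos31622043.1	2	31622043	1E-04	G:T	-5.29	G	13
YPP	Q4	E2	CNT	Chr4pos31966920.1	4	31966920	2E-04	G:C	4.61	C	16
YPP	Q5	E1	HNT	Chr1pos22255654.1	1	22255654	7E-06	G:C	12.02	C	3
YPP	Q6	E1	HNT	Chr2pos34468097.1	2	34468097	4E-05	T:G	6.32	G	15
YPP	Q7	E1	HNT	Chr11pos23922165.1	11	23922165	4E-05	T:C	9.21	C	14
YPP	Q8	E2	HNT	Chr2pos31666003.1	2	31666003	1E-04	T:G	-4.53	T	20
YPP	Q9	E2	HNT	Chr8pos1149355.1	8	1149355	1E-04	C:T	4.63	T	12
YPP	YPP_Rel	E1	Relative	Chr1pos22255654.1	1	22255654	4E-05	G:C	0.54	C	4
YPP	YPP_Rel	E1	Relative	Chr2pos34468097.1	2	34468097	6E-05	T:G	0.30	G	14
YPP	YPP_Rel	E2	Relative	Chr7pos23086735.1	7	23086735	2E-04	C:A	0.32	A	17
HWT	Q10	E1	CNT	Chr2pos484762.1	2	484762	1E-05	C:G	-0.36	C	15
HWT	Q11	E1	CNT	Chr7pos20225421.1	7	20225421	2E-04	T:C	-0.14	T	19
HWT	Q12	E2	CNT	Chr2pos31959843.1	2	31959843	4E-05	A:G	-0.22	A	17
HWT	Q13	E1	HNT	Chr2pos4831761.1	2	4831761	8E-05	C:A	-0.15	C	19
HWT	Q14	E2	HNT	Chr3pos6079159.1	3	6079159	2E-05	C:T	-0.20	C	11
HWT	Q15	E2	HNT	Chr4pos4550145.1	4	4550145	7E-05	C:T	-0.11	C	7
HWT	HWT_Rel	E1	Relative	Chr3pos15905968.1	3	15905968	2E-05	G:A	0.17	A	6
HWT	HWT_Rel	E1	Relative	Chr8pos4667697.1	8	4667697	9E-05	G:C	0.10	C	11
HWT	HWT_Rel	E2	Relative	Chr4pos33782238.1	4	33782238	2E-04	G:A	-0.06	G	19
HWT	HWT_Rel	E2	Relative	Chr5pos29593994.1	5	29593994	3E-04	A:G	-0.07	A	20
HWT	HWT_Rel	E2	Relative	Chr8pos25495868.1	8	25495868	2E-04	G:A	-0.14	G	9
HI	Q16	E1	CNT	Chr1pos6652979.1	1	6652979	2E-04	T:G	-0.08	T	15
HI	Q17	E1	CNT	Chr4pos15947167.1	4	15947167	2E-04	A:G	0.07	G	4
HI	Q18	E2	CNT	Chr1pos29483935.1	1	29483935	5E-05	T:A	-0.10	T	17
HI	Q19	E2	CNT	Chr1pos30060165.1	1	30060165	1E-04	C:T	-0.08	C	23
HI	Q20	E2	CNT	Chr11pos23898551.1	11	23898551	6E-05	C:T	-0.13	C	2
HI	Q21	E2	CNT	Chr11pos24244335.1	11	24244335	1E-04	A:G	-0.13	A	11
HI	Q22	E1	HNT	Chr2pos25528306.1	2	25528306	2E-04	G:T	0.14	T	14
HI	Q23	E1	HNT	Chr2pos34468097.1	2	34468097	1E-04	T:G	0.07	G	15
HI	Q24	E1	HNT	Chr4pos28033149.1	4	28033149	2E-04	C:T	0.10	T	19
HI	Q25	E1	HNT	Chr11pos3631830.1	11	3631830	4E-04	T:C	0.09	C	10
HI	Q26	E2	HNT	Chr1pos4312404.1	1	4312404	3E-05	C:A	-0.12	C	12
HI	Q27	E2	HNT	Chr11pos17764785.1	11	17764785	3E-04	A:C	0.06	C	5
HI	HI_Rel	E1	Relative	Chr2pos23789929.1	2	23789929	4E-05	G:T	0.45	T	14
HI	HI_Rel	E1	Relative	Chr11pos3631830.1	11	3631830	2E-04	T:C	0.34	C	10
HI	HI_Rel	E2	Relative	Chr6pos15730222.1	6	15730222	2E-04	T:C	-0.20	T	9
HI	HI_Rel	E2	Relative	Chr7pos6689342.1	7	6689342	2E-05	G:A	-0.23	G	3
CHALK	Q28	E2	CNT	Chr3pos15967569.1	3	15967569	4E-05	G:T	13.42	G	12
CHALK	Q29	E2	CNT	Chr9pos14091989.1	9	14091989	4E-05	G:A	16.62	G	10
CHALK	Q30	E2	CNT	Chr11pos22646338.1	11	22646338	1E-05	C:G	14.12	C
CHALK	Q31	E2	HNT	Chr1pos39165647.1	1	39165647	1E-04	A:G	39.61	A	14
CHALK	Q32	E2	HNT	Chr2pos33430148.1	2	33430148	1E-04	T:C	27.26	T	15
CHALK	Q33	E2	HNT	Chr3pos1662112.1	3	1662112	1E-04	A:C	-17.80	C	16
CHALK	Q34	E2	HNT	Chr4pos20331507.1	4	20331507	9E-05	T:C	24.36	T	16
CHALK	CHALK_Rel	E2	Relative	Chr2pos18751285.1	2	18751285	6E-07	G:A	10.67	A	6
CHALK	CHALK_Rel	E2	Relative	Chr6pos909702.1	6	909702	7E-05	T:G	8.39	G	18
CHALK	CHALK_Rel	E2	Relative	Chr8pos20389531.1	8	20389531	2E-05	C:G	-8.75	C	10
CHALK	CHALK_Rel	E2	Relative	Chr11pos1113438.1	11	1113438	1E-05	G:A	9.19	A	8
GW	GW5	E2	CNT	Chr5pos5366489.1	5	5366489	1E-06	G:A	0.39	A	6
GW	GW5	E2	HNT	Chr5pos5366489.1	5	5366489	7E-05	G:A	0.30	A	6
GW	GW_Rel	E2	Relative	Chr1pos3609856.1	1	3609856	2E-04	A:G	0.042	G	10
GW	GW_Rel	E2	Relative	Chr7pos25293594.1	7	25293594	5E-04	A:G	0.053	G	20
GL	GL3	E2	CNT	Chr3pos16794259.1	3	16794259	4E-06	A:T	0.32	T	7
GL	GL3	E2	HNT	Chr3pos16794259.1	3	16794259	4E-07	A:T	0.77	T	7
GL	GL_Rel	E2	Relative	Chr3pos33471970.1	3	33471970	2E-05	C:T	0.072	T	21
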