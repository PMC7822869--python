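gene_symbol	ensembl_id	ct_ratio	mdd_ratio	mdd_over_ct	p_value
AC010531.1	ENSG00000131152.4_4	1.109117	0.451195	0.406806	0.020
AC068987.1	ENSG00000260415.3	0.617041	1.035928	1.678864	0.025
AC092835.1	ENSG00000233757.6_3	0.740429	0.890826	1.203121	0.040
ACAD11	ENSG00000240303.7_3	0.442945	0.759169	1.713913	0.043
ACTL6A	ENSG00000136518.16_3	0.588869	0.83387	1.416053	0.035
ANKRD20A2	ENSG00000183148.6_3	0.328245	0.533641	1.625738	0.044
AP000350.4	ENSG00000251357.4_4	0.794562	0.645044	0.811824	0.017
APOL4	ENSG00000100336.17_3	0.76277	1.415282	1.855449	0.033
ARHGAP24	ENSG00000138639.17_2	0.856571	1.10586	1.291032	0.028
ATP10B	ENSG00000118322.12_2	0.668256	0.949887	1.421441	0.037
BBS4	ENSG00000140463.13_3	0.727548	0.934154	1.283976	0.027
BCL7B	ENSG00000106635.7_2	1.074546	1.000904	0.931467	0.042
C14orf119	ENSG00000179933.5_2	0.73052	0.86649	1.186128	0.024
CACNB3	ENSG00000167535.7_2	1.092732	0.961579	0.879977	0.029
CAPN3	ENSG00000092529.23_3	0.618857	0.8293	1.340051	0.042
CDIP1	ENSG00000089486.16_3	1.043427	0.963377	0.923281	0.032
CDK5R2	ENSG00000171450.5_2	0.981479	0.925658	0.943125	0.034
CREM	ENSG00000095794.19_4	0.76757	0.877173	1.142792	0.048
CRISPLD1	ENSG00000121005.8_2	0.546605	0.845734	1.547248	0.041
CEP85	ENSG00000130695.14_2	0.770408	0.951118	1.234563	0.038
CNDP2	ENSG00000133313.14_3	1.032092	0.902963	0.874886	0.036
CWC25	ENSG00000273559.4_2	0.732397	0.952897	1.301066	0.047
CX3CL1	ENSG00000006210.6_2	0.649123	0.903662	1.392127	0.013
CYP46A1	ENSG00000036530.8_2	0.988763	0.906198	0.916496	0.038
DAXX	ENSG00000204209.11_4	1.068359	0.967248	0.905358	0.021
DDX3Y	ENSG00000067048.16_3	0.78034	0.833528	1.06816	0.044
DIABLO	ENSG00000184047.16_3	0.835929	0.982002	1.174744	0.043
DNAH9	ENSG00000007174.17_3	0.661659	0.889836	1.344856	0.049
DPH2	ENSG00000132768.13_2	1.084157	0.956665	0.882405	0.016
EFCAB11	ENSG00000140025.15_3	0.785504	1.073849	1.367084	0.039
EHD1	ENSG00000110047.17_2	1.109755	0.898865	0.809967	0.006
ENDOU	ENSG00000111405.8_2	1.002033	1.600795	1.597547	0.044
FAM212A	ENSG00000185614.4_2	0.936095	0.711428	0.759995	0.025
FAM219A	ENSG00000164970.14_2	1.143265	1.012943	0.886009	0.034
FAM78A	ENSG00000126882.12_2	1.158076	1.008606	0.870932	0.040
FBXL18	ENSG00000155034.18_3	1.340458	1.095543	0.81729	0.024
FCF1	ENSG00000119616.11_2	0.75	1.20057	1.600761	0.033
FGD1	ENSG00000102302.7_2	1.08939	1.007333	0.924676	0.046
GADD45A	ENSG00000116717.11_2	0.898648	1.091988	1.215146	0.045
GALK2	ENSG00000156958.14_3	0.713817	0.875241	1.226142	0.035
GALNT4	ENSG00000257594.3_3	0.565474	0.923666	1.633437	0.032
GDI1	ENSG00000203879.11_2	0.985422	0.90179	0.915131	0.044
GPIHBP1	ENSG00000277494.1_2	0.564343	0.769699	1.363885	0.048
GSG1L	ENSG00000169181.12_4	0.885812	1.14154	1.288693	0.003
GUCA1B	ENSG00000112599.8_2	0.862628	1.521691	1.764017	0.009
HAUS7	ENSG00000213397.10_4	0.615618	0.86666	1.407789	0.047
HSPA2	ENSG00000126803.9_3	1.29328	0.91394	0.706684	0.041
IGSF21	ENSG00000117154.11_3	0.998621	0.940739	0.942038	0.031
IMMT	ENSG00000132305.20_2	0.811733	0.939611	1.157537	0.027
INPP1	ENSG00000151689.12_2	0.702529	0.885719	1.260758	0.018
JMJD4	ENSG00000081692.12_2	0.911505	1.218259	1.336535	0.004
KIAA0040	ENSG00000235750.9_2	0.381431	0.789758	2.070513	0.023
KLHL20	ENSG00000076321.10_3	0.810558	1.045121	1.289384	0.015
KRBA2	ENSG00000184619.3_3	0.856094	1.106994	1.293075	0.001
LACTB2	ENSG00000147592.8_2	0.672986	0.93313	1.386551	0.029
LIMK1	ENSG00000106683.14_2	1.229904	1.050647	0.854251	0.019
LLGL2	ENSG00000073350.13_2	0.529035	0.768594	1.452823	0.029
LRP2	ENSG00000081479.12_2	0.440017	0.777273	1.766463	0.037
LSM1	ENSG00000175324.9_2	0.948025	1.037139	1.093999	0.047
MAP2K2	ENSG00000126934.13_2	1.043799	0.978676	0.937609	0.039
MOG	ENSG00000204655.11_3	0.737132	0.937363	1.271635	0.027
MSH6	ENSG00000116062.14_3	0.749917	0.972315	1.296563	0.041
MTA3	ENSG00000057935.13_2	1.279879	1.067502	0.834065	0.015
MTO1	ENSG00000135297.15_2	0.723714	0.916889	1.266921	0.020
NDE1	ENSG00000072864.14_3	0.630604	0.935422	1.483376	0.007
ODC1	ENSG00000115758.12_3	0.948832	1.050529	1.10718	0.021
OSMR	ENSG00000145623.12_3	0.492132	0.750504	1.525004	0.015
PARP12	ENSG00000059378.12_2	0.524304	0.786383	1.499861	0.022
PCCB	ENSG00000114054.13_3	0.870068	0.946768	1.088155	0.036
PHLDA2	ENSG00000181649.5_2	1.002686	0.690281	0.688432	0.041
PLSCR1	ENSG00000188313.12_3	0.593825	0.791404	1.332722	0.025
PM20D2	ENSG00000146281.5_2	0.834077	0.986752	1.183046	0.043
POPDC3	ENSG00000132429.9_2	0.716706	0.938912	1.310038	0.011
PPARA	ENSG00000186951.16_3	0.907818	1.409824	1.552982	0.048
PPIE	ENSG00000084072.16_3	0.722037	0.916081	1.268745	0.010
PPP1R18	ENSG00000146112.11_2	1.126685	0.970509	0.861385	0.037
PSENEN	ENSG00000205155.7_3	0.79529	0.877975	1.103969	0.040
PTP4A3	ENSG00000184489.11_4	0.96628	0.871331	0.901738	0.044
RBBP4	ENSG00000162521.18_3	0.852028	1.003293	1.177535	0.046
RFT1	ENSG00000163933.9_3	0.881272	1.058105	1.200657	0.025
RGS16	ENSG00000143333.6_2	0.747131	1.081041	1.446923	0.022
RHOQ	ENSG00000119729.11_3	1.32783	1.141333	0.859548	0.043
RILPL2	ENSG00000150977.10_2	1.145368	1.009566	0.881434	0.027
RIPK1	ENSG00000137275.13_2	0.795016	0.952675	1.19831	0.016
RNASE4	ENSG00000258818.3_3	0.496841	0.945895	1.903816	0.042
RNF214	ENSG00000167257.10_3	1.022524	0.873818	0.85457	0.004
RPL6	ENSG00000089009.15_2	0.945796	1.022728	1.081341	0.027
S100PBP	ENSG00000116497.17_3	0.597426	0.997503	1.669666	0.032
SCO2	ENSG00000130489.14_3	0.898872	0.774805	0.861975	0.020
SEC13	ENSG00000157020.17_3	0.799129	0.926857	1.159834	0.046
SEMA6A	ENSG00000092421.16_2	0.733411	0.921617	1.256617	0.036
SH3BP4	ENSG00000130147.15_3	0.782312	0.975496	1.246939	0.015
SHC4	ENSG00000185634.11_2	0.705852	1.152284	1.632473	0.042
SLC39A7	ENSG00000112473.17_3	0.843186	0.94314	1.118543	0.045
SMKR1	ENSG00000240204.2_2	0.938199	1.101026	1.173553	0.034
SMNDC1	ENSG00000119953.12_2	0.673909	0.853418	1.266369	0.033
SPAG1	ENSG00000104450.12_2	0.696272	0.947067	1.360198	0.034
STUM	ENSG00000203685.9_3	1.103296	1.36013	1.232788	0.023
SUSD3	ENSG00000157303.10_3	0.944125	0.582786	0.617277	0.017
SYPL2	ENSG00000143028.8_2	0.253054	0.164774	0.651142	0.009
TAF6	ENSG00000106290.14_3	1.070497	0.988082	0.923012	0.022
TAF6L	ENSG00000162227.7_3	0.925703	0.798461	0.862545	0.046
TBC1D3	ENSG00000197681.8	0.528187	1.078091	2.041115	0.046
TMEM138	ENSG00000149483.11_2	0.545755	0.801324	1.468284	0.010
TMEM230	ENSG00000089063.14_2	0.870686	0.938659	1.078069	0.038
TMEM250	ENSG00000238227.7_4	1.29612	1.078574	0.832156	0.018
TNFSF13	ENSG00000161955.16_3	0.991214	1.133431	1.143478	0.049
TRAPPC5	ENSG00000181029.8_3	1.232167	0.971181	0.788189	0.037
TRIM16	ENSG00000221926.11_4	0.72783	1.020225	1.401735	0.046
TULP3	ENSG00000078246.16_3	0.823316	1.013812	1.231377	0.045
TVP23C-CDRT4	ENSG00000259024.6_3	0.645766	1.116121	1.728368	0.028
TXNIP	ENSG00000265972.5_2	0.798444	0.891237	1.116217	0.049
U2AF1L5	ENSG00000275895.6_4	0.661736	0.927801	1.40207	0.007
ZC3H12A	ENSG00000163874.10_3	0.46926	0.950929	2.026445	0.018
ZNF229	ENSG00000278318.4_3	0.903331	1.162093	1.286453	0.035
ZNF334	ENSG00000198185.11_3	0.537001	0.790072	1.471268	0.047
ZNF610	ENSG00000167554.14_2	0.647825	0.887647	1.370194	0.019
ZNF823	ENSG00000197933.12_3	0.694311	0.896145	1.290696	0.047
ZNF84	ENSG00000198040.10_3	0.566025	1.072708	1.89516	0.040
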