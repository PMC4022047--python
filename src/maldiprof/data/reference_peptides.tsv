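table	observed_mz	printed_calc_mz	adduct	name	precursor	notation
T1	925.481	925.436	H	PDNFMRFamide	FMRF_DROME	R.PDNFMRFa.G
T1	974.592	974.589	H	RLRF peptide 2	SNPF_DROME	R.SPSLRLRFa.G
T1	1182.578	1182.573	H	DPKQDFMRFamide (FMRFamide 2)	FMRF_DROME	R.DPKQDFMRFa.G
T1	1247.658	1247.653	H	Dromyosuppressin (TDVDHVFLRFamide)	NEMS_DROME	R.TDVDHVFLRFa.G
T1	1395.748	1395.753	H	SIFamide (IFa-1)	Q59E62_DROME	A.AYRKPPFNGSIFa.G
T1	1430.745	1430.754	H	CAP-3 AA2-AA15	CP2B_DROME	T.GPSASSGLWFGPRLa.G
T1	1471.791	1471.773	H	MTYamide peptide	NPLP1_DROME	R.YIGSLARAGGLMTYa.G
T1	1531.812	1531.802	H	CAP-3 (CAPA-3)	CP2B_DROME	R.TGPSASSGLWFGPRLa.G
T1	1534.819	1534.834	H	NPLP1-4 (VQQ)	NPLP1_DROME	R.NLGALKSSPVHGVQQ.K
T1	1653.907	1653.908	H	IPNamide	NPLP1_DROME	R.NVGTLARDFQLPIPNa.G
T1	1972.015	1972.017	H	Neuropeptide PDF	PDF_DROME	R.NSELINSLLSLPKNMNDAa.G
T1	1991.044	1991.043	H	QRAamide (NPLP1-3 AA1-AA18)	NPLP1_DROME	R.NVAAVARYNSQHGHIQRAa.G
T1	2094.091	2094.088	H	NPLP1-2 (DPK)	NPLP1_DROME	R.NIATMARLQSAPSTHRDPK.R
T1	2249.130	2249.128	H	NPLP1-3 (GAE)	NPLP1_DROME	R.NVAAVARYNSQHGHIQRAGAE.K
T2	915.399	915.415	H	SDNFMRFamide (FMRFamide 9)	FMRF_DROME	R.SDNFMRFa.G
T2	925.481	925.490	H	Drostatin-3 (Ast-A3)	ALLS_DROME	R.SRPYSFGLa.G
T2	936.463	936.473	H	TK-3 (APTGFTGMRamide)	TACHY_DROME	R.APTGFTGMRa.G
T2	942.584	942.589	H	TK-2 (APLAFVGLRamide)	TACHY_DROME	K.APLAFVGLRa.G
T2	953.529	953.521	H	Drostatin-1 (Ast-A1)	ALLS_DROME	R.VERYAFGLa.G
T2	961.486	961.504	H	TK-5 (APNGFLGMRamide)	TACHY_DROME	R.APNGFLGMRa.G
T2	982.622	982.606	H	sNPF-3 (KPQRLRWamide)	SNPF_DROME	R.KPQRLRWa.G
T2	985.592	985.588	H	sNPF-4 (KPMRLRWamide)	SNPF_DROME	R.KPMRLRWa.G
T2	996.556	996.572	Na	RLRF peptide 2	SNPF_DROME	R.SPSLRLRFa.G
T2	1005.557	1005.512	H	SAPQDFVRSamide (FMRFamide 12)	FMRF_DROME	R.SAPQDFVRSa.G
T2	1015.603	1015.605	H	CAP-2 (CAPA-2)	CP2B_DROME	K.ASGLVAFPRVa.G
T2	1065.560	1065.552	H	TK-1 (APTSSFIGMRamide)	TACHY_DROME	R.APTSSFIGMRa.G
T2	1076.560	1076.568	H	TK-4 (APVNSFVGMRamide)	TACHY_DROME	R.APVNSFVGMRa.G
T2	1112.529	1112.520	H	TPAEDFMRFamide (FMRFamide 7)	FMRF_DROME	R.TPAEDFMRFa.G
T2	1157.554	1157.549	H	Corazonin AA3-AA11	CORZ_DROME	T.FQYSRGWTNa.G
T2	1161.551	1161.558	H	AKH peptide (+ C-term GK)	AKH_DROME	C.pQLTFSPDWGK.R
T2	1186.538	1186.511	H	Drosulfakinin-1 (DSK-1)	DSK_DROME	R.FDDYGHMRFa.G
T2	1253.616	1253.617	H	Drostatin-B5 (Ast-B4)	MIP_DROME	R.DQWQKLHGGWa.G
T2	1276.696	1276.680	H	Drostatin-4 (Ast-A4)	ALLS_DROME	R.TTRPQPFNFGLa.G
T2	1294.681	1294.673	H	CAP-1 (CAPA-1)	CP2B_DROME	R.GANMGLYAFPRVa.G
T2	1324.727	1324.717	H	IFa-2	Q59E62_DROME	A.YRKPPFNGSIFa.G
T2	1329.786	1329.787	H	RLRF peptide 1	SNPF_DROME	K.AQRSPSLRLRFa.G
T2	1369.644	1369.629	H	Corazonin (Crz peptide)	CORZ_DROME	G.pQTFQYSRGWTNa.G
T2	1423.814	1423.827	H	NAP peptide (+ C-term K) (APK)	NPLP1_DROME	R.SVAALAAQGLLNAPK.R
T2	1452.744	1452.736	Na	CAP-3 AA2-AA15	CP2B_DROME	T.GPSASSGLWFGPRLa.G
T2	1603.841	1603.835	H	Drostatin-B3 (Ast-B3)	MIP_DROME	R.RQAQGWNKFRGAWa.G
T2	1658.677	1658.665	H	Drosulfakinin-2 (DSK-2)	DSK_DROME	R.GGDDQFDDYGHMRFa.G
T2	1741.940	1741.962	H	Leucokinin (DLK)	LCK_DROME	R.NSVVLGKKQRFHSWGa.G
T2	2009.982	2009.973	K	Neuropeptide PDF	PDF_DROME	R.NSELINSLLSLPKNMNDAa.G
T2	2176.201	2176.188	H	CAP Propeptide 3	CP2B_DROME	R.GDAELRKWAHLLALQQVLD.K
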