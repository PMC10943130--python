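source	role	gene	circ_id	frame	infinite	peptide	context
TABLE1_T1185B	bsj	ANXA6	hsa_circ_0074614	0	TRUE	VQDLIADLK	VVLLQGTREEDDVVSEDLVQQD- > V[QD]LIADLK < -YELTGKFERLIVGLMRP
TABLE1_T1185B	bsj	CBLL1	hsa_circ_0081903	0	FALSE	DTFFGTFR	GMTVKGVSCLQISEDFL- > DTFFGTF[R] < -RI
TABLE1_T1185B	bsj	CDC73	hsa_circ_0111569	0	TRUE	TTENIPVVRR	KEETEGFKIDTMGTYHGMTLKSV- > [TT]ENIPVVRR < -PDRKDLLGYLNGEAS
TABLE1_T1185B	bsj	CLASP2	hsa_circ_0123550	2	FALSE	LETLGDKECI	SFSVWDEHFKTILLLL- > LETLGDK[EC]I < -
TABLE1_T1185B	bsj	CTNNB1	hsa_circ_0003137	1	FALSE	RVFEVYHTTVLK	MATKKA- > [R]VFEVYHTTVLK < -IQRGQWLLKLI
TABLE1_T1185B	bsj	CTNNB1	hsa_circ_0004030	1	FALSE	RVFEVYHTTVLK	SWMGCLQVTAISWPGLILTCKSSF- > [R]VFEVYHTTVLK < -IQRGQWLLKLI
TABLE1_T1185B	bsj	CTSB	hsa_circ_0083357	1	FALSE	STMSTNGIPRGR	GAGPLSIPCRMSW- > STMSTNGIPRG[R] < -GRGREGT
TABLE1_T1185B	bsj	CTSB	hsa_circ_0083357	1	FALSE	STNGIPRGR	GAGPLSIPCRMSWSTM- > STNGIPRG[R] < -GRGREGT
TABLE1_T1185B	bsj	ETV5	hsa_circ_0068440	2	TRUE	FVPDFQSDNR	QEAWLAEAQVPDDEQ- > FVPDFQSDN[R] < -GSLFPQKLLNAETSQSGIRDAEST
TABLE1_T1185B	bsj	GAS7	hsa_circ_0042080	0	FALSE	EAWNGPPSAGR	WERPSSSPGIPASPGSHRSSLPPT- > [E]AWNGPPSAGR < -RKPDGHPSTWLAEL
TABLE1_T1185B	bsj	KIAA0226	hsa_circ_0068719	1	FALSE	SSITGLSVTR	MVAWSGFAGTCRA- > SSITGLSVT[R] < -REHWQLLGNLKTTVEGLVSTNSPN
TABLE1_T1185B	bsj	LIN9	hsa_circ_0016709	0	FALSE	EIYSNNVNTR	ADVSQFKDLPDEIPLPLVIGTKVT- > [E]IYSNNVNTR < -
TABLE1_T1185B	bsj	LINC00221	hsa_circ_0101415	1	FALSE	AAAAFRFPR	MPARSWLGE- > AAAAFRFP[R] < -DFCVCAHIDVPTLCPSQ
TABLE1_T1185B	bsj	LINC00221	hsa_circ_0101415	1	FALSE	EAAAAFRFPR	MPARSWLG- > EAAAAFRFP[R] < -DFCVCAHIDVPTLCPSQ
TABLE1_T1185B	bsj	LINC00221	hsa_circ_0101416	0	FALSE	AAAAFRFPR	MPARSWLGE- > AAAAFRFP[R] < -M
TABLE1_T1185B	bsj	LINC00221	hsa_circ_0101416	0	FALSE	EAAAAFRFPR	MPARSWLG- > EAAAAFRFP[R] < -M
TABLE1_T1185B	bsj	NOD1	hsa_circ_0079703	1	FALSE	VPAPPSLTR	MTTSRPKMRRLC- > VPAPPSLT[R] < -GCAE
TABLE1_T1185B	bsj	PAFAH1B2	hsa_circ_0095083	1	FALSE	STTDLFWTVK	MENWRILSL- > [S]TTDLFWTVK < -TKSLMYCSWETPWCS
TABLE1_T1185B	bsj	PKNOX1	hsa_circ_0061852	2	FALSE	QTPFAFHPR	VVTPQGQVVTQTLSPGTIRIQNS- > [QT]PFAFHPR < -
TABLE1_T1185B	bsj	PKNOX1	hsa_circ_0116109	2	FALSE	QTPFAFHPR	KTKMNSETLLSGEPGSPYSPVQS- > [QT]PFAFHPR < -
TABLE1_T1185B	bsj	PKNOX1	hsa_circ_0116112	2	FALSE	QTPFAFHPR	TPVNMNVDSLQSLSSDGATLAVQ- > [QT]PFAFHPR < -
TABLE1_T1185B	bsj	PTPRG	hsa_circ_0066402	0	FALSE	NTASMAGGFLLR	MAQRAL- > NTASMAGGFLL[R] < -HVTSCMEAWPVSSPALFVPSQPAP
TABLE1_T1185B	bsj	PTPRG	hsa_circ_0066406	0	FALSE	NTASMAGGFLLR	MAQRAL- > NTASMAGGFLL[R] < -CLWS
TABLE1_T1185B	bsj	PTPRG	hsa_circ_0124401	0	FALSE	NTASMAGGFLLR	MAQRAL- > NTASMAGGFLL[R] < -YYRTCSD
TABLE1_T1185B	bsj	RFWD2(COP1)	hsa_circ_0015364	0	FALSE	DLYNGSSIVSR	YNSVRPLATLSYAS- > DLYNGSSIVS[R] < -QRNSLGIIAR
TABLE1_T1185B	bsj	RFWD2(COP1)	hsa_circ_0015366	0	FALSE	DLYNGSSIVSR	YNSVRPLATLSYAS- > DLYNGSSIVS[R] < -NHMQPNYRFLWNSSRLQEEIRESN
TABLE1_T1185B	bsj	RFWD2(COP1)	hsa_circ_0111261	0	FALSE	DLYNGSSIVSR	YNSVRPLATLSYAS- > DLYNGSSIVS[R] < -K
TABLE1_T1185B	bsj	RFWD2(COP1)	hsa_circ_0111262	1	FALSE	DLYNGSSIVSR	YNSVRPLATLSYAS- > DLYNGSSIVS[R] < -TSGTMMNRSGDSGAS
TABLE1_T1185B	bsj	STAT3	hsa_circ_0043818	1	TRUE	TIYEESSSFFR	SIAASCKSRMFSIS- > TIYEESSSFF[R] < -VSGAAAAQTGRGSRGFRRRSRGNK
TABLE1_T1185B	bsj	STAT3	hsa_circ_0106859	1	FALSE	TIYEESSSFFR	SIAASCKSRMFSIS- > TIYEESSSFF[R] < -MAQWNQLQQLDTRYLEQLHQLYSD
TABLE1_T1185B	distractor	CTNNB1			FALSE	EVYHTTVLK
TABLE1_T1185B	distractor	CTNNB1			FALSE	HTTVLKIQR
TABLE1_MEL1	bsj	ABCA2	hsa_circ_0089621	2	FALSE	RLKEPSTQR	ISWVYSVAMTIQHIVAEKEH- > RLK[EP]STQR < -RP
TABLE1_MEL1	bsj	CCAR1	hsa_circ_0018553	1	FALSE	VLSKGKPPK	ISAASITPLLQTQPQPLLQQPQQK- > [V]LSKGKPPK < -
TABLE1_MEL1	bsj	CEP57L1	hsa_circ_0130265	1	FALSE	KLRDPTDSTLR	MGLSSCKN- > KLRDPTDSTL[R] < -AWYLVQT
TABLE1_MEL1	bsj	CTNNB1	hsa_circ_0003137	1	FALSE	RVFEVYHTTVLK	MATKKA- > [R]VFEVYHTTVLK < -IQRGQWLLKLI
TABLE1_MEL1	bsj	CTNNB1	hsa_circ_0004030	1	FALSE	RVFEVYHTTVLK	SWMGCLQVTAISWPGLILTCKSSF- > [R]VFEVYHTTVLK < -IQRGQWLLKLI
TABLE1_MEL1	bsj	MALAT1	hsa_circ_0096124	2	FALSE	KLLHGVKNVFK	M- > [KL]LHGVKNVFK < -RKLRERTTEPRINT
TABLE1_MEL1	bsj	PDIA3	hsa_circ_0035034	2	FALSE	RVSSYFVLH	LLERFLLLLSELLKERSLSCRRSS- > [R]VSSYFVLH < -ISLTSLRTRLWHIQSK
TABLE1_MEL1	bsj	SAE1	hsa_circ_0051662	2	FALSE	ILAQEIVKV	MAPVCAVVGG- > ILAQEIV[KV] < -LLLRDGPSVCGGWRDFGTGNCEG
TABLE1_MEL1	bsj	PPP2R3A	hsa_circ_0122039	2	FALSE	KVSLSFTEK	SPVGDKAKDTTSAVLIQQTPEVI- > [KV]SLSFTEK < -
TABLE1_MEL1	bsj	TOPBP1	hsa_circ_0121989	1	FALSE	KSLAAELLVLK	MYTPHCART- > K[S]LAAELLVLK < -
TABLE1_MEL1	bsj	WARS	hsa_circ_0033185	2	FALSE	VLTRLLNK	MPRTSSPVALTSTRLSYSLTWTTW- > [V]LTRLLNK < -SSDLRPAVNVVPER
TABLE1_MEL1	bsj	WARS	hsa_circ_0033189	1	FALSE	VLTRLLNK	SDGESAALESARPAPLLILLPVCM- > [V]LTRLLNK < -SSDLRPAVNVVPER
TABLE1_MEL1	bsj	ZMYM4	hsa_circ_0113154	2	FALSE	RVVVSWIQK	DKAANQVEETLHTHLPQTPETNF- > [RV]VVSWIQK < -CLKI
TABLE1_MEL1	distractor	CTNNB1			FALSE	VYHTTVLK
TABLE2_LUNG	bsj	ABCC1	hsa_circ_0038107	1	FALSE	KRQPVKVVY	MSRSMGE- > K[R]QPVKVVY < -SSKDPAQPKESSKVDAN
TABLE2_LUNG	bsj	ANKRD10	hsa_circ_0030908	0	FALSE	VANGAHVEI	PIHKAARSGSLECISAL- > VANGAHV[E]I < -VRVKLPFTRQLALGA
TABLE2_LUNG	bsj	BABAM1	hsa_circ_0049967	0	FALSE	TFNYLPGPV	GLTSDPRELCSCLYDLETASCS- > TF[N]YLPGPV < -RGNVTAKAGVVQRLQNQR
TABLE2_LUNG	bsj	CTNNB1	hsa_circ_0003137	1	FALSE	RVFEVYHTTVLK	MATKKA- > [R]VFEVYHTTVLK < -IQRGQWLLKLI
TABLE2_LUNG	bsj	CTNNB1	hsa_circ_0004030	1	FALSE	RVFEVYHTTVLK	SWMGCLQVTAISWPGLILTCKSSF- > [R]VFEVYHTTVLK < -IQRGQWLLKLI
TABLE2_LUNG	bsj	EIF4B	hsa_circ_0026498	2	TRUE	DRAKKKNKKGKTISL	DRRDDRSWSSRDDYSRDDYRRD- > DR[A]KKKNKKGKTISL < -TDFLAEDGGTGG
TABLE2_LUNG	bsj	HSP90AB1	hsa_circ_0076651	0	TRUE	ILDKKVEKL	EESKAKFENLCKLMKE- > ILDKKVE[KL] < -GIHEDSTNRRRLSELLRYHTSQS
TABLE2_LUNG	bsj	LIAS	hsa_circ_0069480	1	FALSE	ETVPELQR	AIEKVALSGLDVYAHNV- > ETVPELQ[R] < -YA
TABLE2_LUNG	bsj	MALAT1	hsa_circ_0096124	2	FALSE	KLLHGVKNVFK	M- > [KL]LHGVKNVFK < -RKLRERTTEPRINT
TABLE2_LUNG	bsj	NFKB1	hsa_circ_0070531	1	FALSE	TSLPLSSKL	MIC- > T[S]LPLSSKL < -QSIKILILQNQPLCLSS
TABLE2_LUNG	bsj	NPLOC4	hsa_circ_0046209	1	FALSE	FTEAETHSY	WWRMRLISTSANRTGR- > FTEAETHS[Y] < -NSCPVPGWSEADHSNKERNSSNIF
TABLE2_LUNG	bsj	PPP2R3A	hsa_circ_0122039	2	FALSE	KVSLSFTEK	SPVGDKAKDTTSAVLIQQTPEVI- > [KV]SLSFTEK < -
TABLE2_LUNG	bsj	PTPRG	hsa_circ_0066402	0	FALSE	ASM(Ox)AGGFLLR	MAQRALNT- > ASMAGGFLL[R] < -HVTSCMEAWPVSSPALFVPSQPAP
TABLE2_LUNG	bsj	PTPRG	hsa_circ_0066406	0	FALSE	ASM(Ox)AGGFLLR	MAQRALNT- > ASMAGGFLL[R] < -CLWS
TABLE2_LUNG	bsj	PTPRG	hsa_circ_0124401	0	FALSE	ASM(Ox)AGGFLLR	MAQRALNT- > ASMAGGFLL[R] < -YYRTCSD
TABLE2_LUNG	bsj	SAE1	hsa_circ_0051662	2	FALSE	ILAQEIVKV	MAPVCAVVGG- > ILAQEIV[KV] < -LLLRDGPSVCGGWRDFGTGNCEG
TABLE2_LUNG	bsj	SCRN1	hsa_circ_0079683	0	FALSE	SALTFQSTK	GVSVLPQNRSSPCIHYFTGTPDPS- > [S]ALTFQSTK < -FQGPMP
TABLE2_LUNG	bsj	SNX6	hsa_circ_0008747	0	TRUE	SELFDKTRLK	LGTQDSTDICKFFLKV- > SELFDKT[RL]K < -AINVDLQSDAALQVDISDALSE
TABLE2_LUNG	bsj	TOPBP1	hsa_circ_0121989	1	FALSE	KSLAAELLVLK	MYTPHCART- > K[S]LAAELLVLK < -
TABLE2_LUNG	bsj	YAP1	hsa_circ_0004881	0	FALSE	KTSSGQRYFLK	MA- > KTSSGQRYFL[K] < -PVLMQALQEP
TABLE2_LUNG	bsj	ZMYM4	hsa_circ_0113154	2	FALSE	RVVVSWIQK	DKAANQVEETLHTHLPQTPETNF- > [RV]VVSWIQK < -CLKI
TABLE2_LUNG	bsj	(Intergenic)	hsa_circ_0140588	0	FALSE	DIRKKLFLR	LGVCLVSLRWWRHACLPNMW- > DIR[KK]LFLR < -N
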