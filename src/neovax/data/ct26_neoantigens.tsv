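# Published CT26 neoantigen set (31 records) encoded by the 31-segment vaccine.
# sequence uses mutant-first bracket notation [mut/wt]; maf_pct is the tumor
# variant-allele fraction; mhc1_ic50 in nM; mhc2_score is the class-II rank.
id	gene	sequence	rna_mut	rna_wt	maf_pct	mhc1_ic50	mhc2_score
1	Phf3	PGPQNFPPQNMF[G/E]FPPHLSPPLLPP	6	10	57	41.5	48.7
2	Zeb1	GAQEEPQVEPLD[L/F]SLPKQQGELLER	8	1	36	121.0	47.5
3	Trappc12	AVFAGSDDPFAT[A/P]LSMSEMDRRNDA	5	21	26	457.9	12.7
4	Aldh18a1	HSGQNHLKEMAI[P/S]VLEARACAAAGQ	12	7	51	13035.9	0.05
5	E2f8	ILPQAPSGPSYA[I/T]YLQPAQAQMLTP	3	5	32	320.5	6.8
6	Gid8	MSYAEK[P/S]DEITKDEWMEKL	7	31	26	67.0	49.8
7	Hdac2	GAGKGKYYAVNF[P/S]MRDGIDDESYGQ	29	30	40	39.48	40.5
8	Ttl	YRGADKLCRKAS[L/S]VKLVKTSPELSE	4	8	46	4768.9	0.2
9	Haus6	DSNLQARLTSYE[A/T]LKKSLSKIREES	29	9	33	18.2	7.49
10	Ndc1	HSFIHAAMGMAV[A/T]WCAAIMTKGQYS	3	1	70	15203.7	0.84
11	Glud1	LRTAAYVNAIEK[V/I]FKVYNEAGVTFT	353	89	68	141.15	9.4
12	G2e3	FEGSLAKNLSLN[S/F]QAVKENLYYEVG	12	15	53	467.9	21.1
13	Cad	DPRAAYFRQAEN[G/D]MYIRMALLATVL	11	3	52	2660.3	0.7
14	Dars2	LRSQMVMKMREY[L/F]CNLHGFVDIETP	6	7	46	3795.6	0.39
15	Smarcd1	DLLAFERKLDQT[I/V]MRKRLDIQEALK	16	2	46	11015.8	0.99
16	Zfp955b	IKREKCWKD[V/A]TY[S/P]ESFHTLESVPAT	2	16	45	271.8	9.2
17	Rwdd2b	GRSSQVYFTINV[S/N]LDLSEAAVVTFS	2	9	45	143.0	8.6
18	Slc20a1	KPLRRNNSYTSY[T/I]MAICGMPLDSFR	50	47	42	118.0	3.5
19	Ddx27	TTCLAVGGLDVK[S/F]QEAALRAAPDIL	13	16	41	8042.7	0.6
20	Top3a	IYEFDYHLYGQN[V/I]TMIMTSVSGHLL	1	1	41	124.9	11.4
21	Slc41a2	PDSFSIPYLTAL[G/D]DLLGTALLALSF	2	5	40	134.8	24.5
22	Ttc39a	YATILEMQAMMT[F/L]DPQDILLAGNMM	8	0	37	4108.0	0.2
23	Mtch1	SWIHCWKYLSVQ[G/S]SQLFRGSSLLFRR	160	226	36	13.46	2.2
24	Suv39h2	YDNKGITYLFDL[D/Y]YESDEFTVDAAR	2	7	36	344.48	33.6
25	Tomm70a	AQAAKNKGNKYF[K/Q]AGKYEQAIQCYT	17	41	35	459.4	5.2
26	Csnk2b	QPMLPIGLSDIP[G/D]EAMVKLYCPKCM	79	146	34	202.2	11.8
27	Caprin2	HRGAIYGSSWKY[S/F]TFSGYLLYQD	1	1	31	36.8	50.7
28	Dhx35	VIQTSKYYMRDV[T/I]AIESAWLLELAP	5	11	29	67.5	0.7
29	Xpot	PRGVDLYLRILM[A/P]IDSELVDRDVVH	17	53	28	41.5	4.7
30	Dclre1c	QIEQDALCPQDT[H/Y]CDLKSRAEVNGA	6	6	40	69.1	26.3
31	Noc3l	ALASAILSDPES[H/Y]IKKLKELRSMLM	5	3	60	101.2	10.7
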