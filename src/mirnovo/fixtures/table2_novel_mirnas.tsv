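tissue	chromosome	name	sequence	mirna_length	read_count	precursor_start	precursor_end	strand	precursor_length	gc_percent	mfei
brain	Chr1	Dre-mir-nov49	AGAGGCUGUCCGAGUGCUGAU	21	156	10303253	10303335	+	83	49.4	-1.56
brain	Chr20	Dre-mir-nov8	GACCUGUAACCAUUGACUUCCU	22	102	962031	962117	+	87	36.78	-1.4
brain	Chr3	Dre-mir-nov46	AAAAGCGUACCAAACUGAACCGU	23	122	46496327	46496412	+	86	48.84	-1.3
brain	Chr17	Dre-mir-nov19	AGACUAGUAGCCAUUGAGAUCUU	23	264	20769194	20769271	-	78	33.33	-1.27
brain	Chr18	Dre-mir-nov16	UGUUUUUUUAGGUUUUGAUUUUU	23	1142	45964887	45964967	+	81	33.33	-1.26
brain	Chr4	Dre-mir-nov38	GAAUAACUCAAACCGGAGGACU	22	106	31535442	31535523	+	82	47.56	-1.26
brain	Chr4	Dre-mir-nov42	AAUAACUCAAACCAGAGGACU	21	126	54513045	54513126	+	82	43.9	-1.19
brain	Chr18	Dre-mir-nov15	UUUCCAGAAAGGUCUGUAUGUGU	23	130	26647915	26647993	+	79	46.84	-1.16
brain	GRCZ10_NA262	Dre-mir-nov2	AGACUCUCCAGUACACUGGCCCU	23	862	744	825	-	82	58.54	-1.16
brain	Chr10	Dre-mir-nov25	GAAAACCUGUAACCAUUGACUUCU	24	221	29746032	29746122	+	91	35.16	-1.14
brain	Chr20	Dre-mir-nov10	AAACUUGUAAUCACUGACUUCCU	23	125	35014623	35014703	+	81	33.33	-1.12
brain	Chr2	Dre-mir-nov48	AAUGACUCAAACCCAAGGACUCG	23	1182	8746947	8747032	+	86	40.7	-1.1
brain	Chr6	Dre-mir-nov29	AAACUCUGCAGGACACCAGCUGU	23	268	18113026	18113108	+	83	46.99	-1.05
brain	Chr17	Dre-mir-nov18	AAACUCUGCAGGACACCAGCUG	22	748	47039884	47039964	+	81	46.91	-1.02
brain	Chr4	Dre-mir-nov39	UAAACUCUGCAGGACACCAGCUG	23	1020	42571226	42571306	+	81	46.91	-1.02
brain	Chr6	Dre-mir-nov30	ACUGUACAGACUACUGCCUUGC	22	361	41457248	41457346	+	99	45.45	-0.98
brain	Chr18	Dre-mir-nov17	ACUCUUCACUCGUCUGUGUUCA	22	116	50849750	50849835	-	86	55.81	-0.96
brain	Chr23	Dre-mir-nov3	UCAAAAGGCGUACCAAACUGUAC	23	155	18099730	18099807	-	78	43.59	-0.95
brain	Chr5	Dre-mir-nov37	UCCAUCAGUCACGUGACCUACCA	23	7106	35345784	35345875	-	92	51.09	-0.94
brain	Chr5	Dre-mir-nov33	GGCCCGUCCGGUGCGCUCGGAUCC	24	767	824650	824740	-	91	84.62	-0.93
brain	Chr5	Dre-mir-nov31	UAAACUCUGCAGGACACCAGCUGU	24	158	10220904	10221001	+	98	46.94	-0.93
brain	Chr5	Dre-mir-nov32	GAUGACUCAAACCCAAGGACUCA	23	115	15221789	15221886	+	98	39.8	-0.89
brain	Chr8	Dre-mir-nov28	AAUGACUCAAACCCAAGGACUCGU	24	108	2766509	2766596	+	88	44.32	-0.88
brain	Chr4	Dre-mir-nov44	AGUGAGGUCCUCGGAUCGGCCC	22	1835	76320181	76320279	+	99	68.69	-0.87
brain	Chr22	Dre-mir-nov4	AACGACUCAAGAACCAGAAGACU	23	315	18571986	18572067	+	82	46.34	-0.86
pineal_dark	Chr1	Dre-mir-nov83	AUCAGCACUCGGACAGCCUCUU	22	173	10303251	10303335	+	85	50.59	-1.53
pineal_dark	Chr17	Dre-mir-nov59	AGACUAGUAGCCAUUGAGAUCUU	23	101	20769194	20769271	-	78	33.33	-1.27
pineal_dark	Chr18	Dre-mir-nov58	UGUUUUUUUAGGUUUUGAUUUUU	23	381	45964887	45964967	+	81	33.33	-1.26
pineal_dark	Chr9	Dre-mir-nov66	UACGGGCUGAAUUUAGACAAAUU	23	177	5548615	5548705	+	91	27.47	-1.25
pineal_dark	Chr24	Dre-mir-nov52	UAACGUUUCGAGCCCACUGACUG	23	118	1825424	1825498	-	75	46.67	-1.19
pineal_dark	GRCZ10_NA262	Dre-mir-nov51	AGACUCUCCAGUACACUGGCCCUC	24	997	743	826	-	84	58.33	-1.14
pineal_dark	Chr12	Dre-mir-nov62	UUUCCGGAAAGGUCUGUAUGUGC	23	1654	44383412	44383489	+	78	47.44	-1.14
pineal_dark	Chr4	Dre-mir-nov77	GAAUAACUCAAACCGGAGGACU	22	103	49472235	49472316	+	82	46.34	-1.11
pineal_dark	Chr6	Dre-mir-nov72	UACGGAUAGAAUCAGCGGAGCGA	23	221	56909252	56909333	+	82	60.98	-1.11
pineal_dark	Chr8	Dre-mir-nov70	AACCUGUAACCAUUGACUUCCU	22	140	10454696	10454780	+	85	38.82	-1.04
pineal_dark	Chr1	Dre-mir-nov84	UAAAGCGUACCAAACUGAACCGU	23	150	41154258	41154343	+	86	46.51	-1.00
pineal_dark	Chr11	Dre-mir-nov63	GCUGAAGUCAUUAUUAUUAGGGC	23	116	5486604	5486685	+	82	35.37	-0.98
pineal_dark	Chr6	Dre-mir-nov71	ACUGUACAGACUACUGCCUUGC	22	220	41457248	41457346	+	99	45.45	-0.98
pineal_dark	Chr4	Dre-mir-nov76	GCAGAGAGAAAUGUCUAUGGCUU	23	1712	5403781	5403855	+	75	48.00	-0.97
pineal_dark	Chr5	Dre-mir-nov74	UCCAUCAGUCACGUGACCUACCA	23	15880	35345784	35345875	-	92	51.09	-0.94
pineal_dark	Chr20	Dre-mir-nov54	CUCAUCCCUCUGCUCUAUCCCCU	23	115	37928243	37928325	+	83	50.60	-0.93
pineal_dark	Chr8	Dre-mir-nov69	AAUGACUCAAACCCAAGGACUCG	23	224	2766510	2766595	+	86	44.19	-0.90
pineal_dark	Chr12	Dre-mir-nov61	AACGACUCAAGAGCCAGAAGACU	23	323	3216161	3216240	+	80	45.00	-0.88
pineal_dark	Chr20	Dre-mir-nov55	CAGGGGGUCGGGAAGCACUGCCU	23	4876	48676465	48676553	-	89	58.43	-0.85
pineal_light	Chr1	Dre-mir-nov100	AUCAGCACUCGGACAGCCUCUU	22	100	10303251	10303335	+	85	50.59	-1.53
pineal_light	Chr9	Dre-mir-nov91	UACGGGCUGAAUUUAGACAAAUU	23	101	5548615	5548705	+	91	27.47	-1.25
pineal_light	GRCZ10_NA262	Dre-mir-nov85	AGACUCUCCAGUACACUGGCCCUC	24	491	743	826	-	84	58.33	-1.14
pineal_light	Chr12	Dre-mir-nov89	UUUCCGGAAAGGUCUGUAUGUGC	23	1075	44383412	44383489	+	78	47.44	-1.14
pineal_light	Chr6	Dre-mir-nov94	UACGGAUAGAAUCAGCGGAGCGA	23	130	56909252	56909333	+	82	60.98	-1.11
pineal_light	Chr4	Dre-mir-nov97	GCAGAGAGAAAUGUCUAUGGCUU	23	903	5403781	5403855	+	75	48.00	-0.97
pineal_light	Chr5	Dre-mir-nov95	UCCAUCAGUCACGUGACCUACCA	23	8256	35345784	35345875	-	92	51.09	-0.94
pineal_light	Chr4	Dre-mir-nov99	AGUGAGGUCCUCGGAUCGGCCCC	23	144	76320181	76320279	+	99	68.69	-0.87
pineal_light	Chr20	Dre-mir-nov88	CAGGGGGUCGGGAAGCACUGCCU	23	2104	48676465	48676553	-	89	58.43	-0.85
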