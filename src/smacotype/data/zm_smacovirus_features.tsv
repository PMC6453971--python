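virus	accession	genome_length_nt	rep_aa	cp_aa	nonanucleotide	RCR-I	RCR-II	RCR-III	Walker-A	Walker-B	Walker-C
PkSmV1-ZM09-64	LC386203	2544	259	368	AGGTCTTAC	ATVWVD	HFQ	FRGYVYK	SRGNWGKT	LVDTP	VLCN
CcSmV1-ZM09-86	LC386195	2691	284	369	AATGATTAC	ATIDR	HWQ	CRFYETK	PTGNIGKS	IIDIP	VMTN
CcSmV1-ZM09-96	LC386196	2659	268	182	AAAAATTAC	VTMGR	HWQ	VRFYEAK	ETGNRGKS	VIDIP	VLTN
PcSmV2-ZM09-71	LC386204	2766	271	359	AATGATTAC	CTVPN	HFQ	LRCYVEK	RVGGRGKT	VIDMP	VITN
PcSmV3-ZM09-51	LC386205	2540	269	312	TAGTGTTAC	MTAPR	HWQ	CRIYEAK	ETGNVGKS	IIDVP	VMTN
PcSmV3-ZM09-74	LC386197	2488	245	330	TAGTATTAC	GTAPR	HWQ	IRIYEAK	ETGNVGKS	IIDVP	VMTN
PkSmV3-ZM09-76	LC386198	2542	269	330	TAGTGTTAC	MTAPR	HWQ	CRIYEAK	ETGNRGKS	IIDVP	VMTN
CcSmV4-ZM09-95	LC386199	2656	260	271	TAGTATTAC	LTIPR	HWQ	VVVYCRK	VRGGHGKT	WIDLP	VTTN
CcSmV5-ZM09-83	LC386200	2617	261	354	TAGTATTAC	GTISA	HYQ	YTVYCKK	GGGHGKT	WIDLP	VTTN
PcSmV6-ZM09-72	LC386201	2613	269	353	TAGTATTAC	GTISA	HFQ	YYIYCKK	VGGAHGKT	WIDIP	VTTN
CcSmV6-ZM09-96	LC386202	2537	269	354	TAGTATTAC	GTISA	HFQ	YCIYCKK	VGGAHGKT	WIDLP	VTTN
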