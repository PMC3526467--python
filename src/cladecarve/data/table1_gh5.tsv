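subfamily	historical	n_sequences	tax_distribution	ec_list	pdb
GH5_1	A1	133	Archaea Bacteria Eukaryota	3.2.1.4;3.2.1.73;3.2.1.91	2ZUN
GH5_2	A2	245	Bacteria Eukaryota	3.2.1.4;3.2.1.132	2A3H
GH5_4	A3+A4	160	Bacteria Eukaryota	3.2.1.4;3.2.1.151;3.2.1.73;3.2.1.8	2JEQ
GH5_5	A5+A6	123	Bacteria Eukaryota	3.2.1.4	IGZJ
GH5_7	A7	133	Archaea Bacteria Eukaryota	3.2.1.25;3.2.1.78;2.4.1.-	IRH9
GH5_8	A8	71	Bacteria Eukaryota	3.2.1.78	2WHL
GH5_9	A9	107	Eukaryota	3.2.1.58;3.2.1.75;3.2.1.21	3N9K
GH5_10	A10	19	Bacteria Eukaryota (Metazoa)	3.2.1.78	2C0H
GH5_11		19	Eukaryota (Plants;Fungi)	ND
GH5_12		42	Bacteria Eukaryota	3.2.1.21;3.2.1.45
GH5_13		59	Bacteria	ND
GH5_14		15	Eukaryota (Plants)	3.2.1.58
GH5_15		10	Eukaryota (Fungi)	3.2.1.75
GH5_16		10	Eukaryota (Fungi)	3.2.1.164
GH5_17		5	Bacteria	3.2.1.78
GH5_18		24	Bacteria	ND
GH5_19		23	Archaea	ND
GH5_20		17	Eukaryota (Stramenopiles)	ND
GH5_21		10	Bacteria	3.2.1.8
GH5_22		12	Bacteria Eukaryota	3.2.1.4
GH5_23		5	Eukaryota (Fungi)	3.2.1.149;3.2.1.168
GH5_24		5	Eukaryota (Fungi)	ND
GH5_25		16	Bacteria	3.2.1.4;3.2.1.78	3MMW
GH5_26		17	Bacteria	3.2.1.4;3.2.1.73
GH5_27		5	Eukaryota (Metazoa;Fungi)	3.2.1.123
GH5_28		8	Bacteria	3.2.1.123	2OSX
GH5_29		5	Bacteria	3.2.1.123
GH5_30		5	Eukaryota (Fungi)	ND
GH5_31		5	Eukaryota (Fungi)	3.2.1.-
GH5_32		5	Eukaryota (Plants;Stramenopiles)	ND
GH5_33		9	Eukaryota (Stramenopiles)	ND
GH5_34		5	Bacteria	3.2.1.-	2Y8K
GH5_35		5	Bacteria	ND
GH5_36		23	Bacteria	3.2.1.73;3.2.1.78	IVJZ
GH5_37		19	Bacteria	3.2.1.4;3.2.1.73;3.2.1.74	ICEN
GH5_38		10	Bacteria	3.2.1.-
GH5_39		7	Bacteria	3.2.1.4
GH5_40		8	Bacteria	ND
GH5_41		14	Bacteria	ND
GH5_42		9	Bacteria	ND
GH5_43		11	Bacteria	ND
GH5_44		24	Bacteria	ND
GH5_45		5	Bacteria	ND
GH5_46		15	Bacteria	3.2.1.-
GH5_47		6	Bacteria	ND
GH5_48		18	Bacteria	3.2.1.-
GH5_49		20	Eukaryota (Fungi)	ND
GH5_50		7	Eukaryota (Fungi)	ND
GH5_51		5	Bacteria Eukaryota (Fungi)	ND
GH5_52		6	Bacteria	3.2.1.74
GH5_53		6	Bacteria	3.2.1.74
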