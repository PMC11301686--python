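section	sequence	mono_mh	z2_mz	V_b_barani	V_darevskii	M_b_bulgardaghica	M_b_albizona	M_xanthina	M_l_obtusa	D_palaestinae	notes
K	pEKW	444.224		x	x	x	x	x	x	x	2MH+1 (m/z 887.441)
K	pEKW_ox_	460.219		x	x	x	x	x	x	x	Trp oxidation
K	pEKWP	541.277				x	x	x	x	x
K	pEKWPSPK	853.457	427.232			x	x		x	x
K	pEKWPSPKVPP	1146.631	573.819			x	x		x
K	pEKWPVPGP	891.472	446.240			x	x	x	x
K	pEKWPVPGPEIPP	1327.705	664.356			x	x	x	x
K	pEKWPM_ox_PGPEIPP	1375.672	688.340							x	Met oxidation
K	pEKWLDPEIPP	1205.620	603.314		x
N	pENW	430.172		x	x	x	x	x		x	2MH+1 (m/z 859.337)
N	pENWP	527.225			x	x	x	x
N	pENWPGP	681.299			x
N	pENWPGPK	809.394	405.201		x			x
N	pENWPSP	711.310				x	x	x
N	pENWPSPK	839.405	420.206			x	x	x			known as BPP-7b
N	pENWPSPKVPP	1132.579	566.793			x	x	x			known as BPP-10e
R	pERW	472.230		x	x	x	x	x	x		2MH+1 (m/z 859.337)
R	pERWPGP	723.357		x						x
R	pERWPGPEIPP	1159.590	580.299							x
R	pERWPGPK	851.453	426.230	x						x
R	pERWPGPKVPP	1144.626	572.817	x						x
R	pERW_ox_PGPKVPP	1160.621	580.814	x						x	Trp oxidation
R	pERW_diox_PGPKVPP	1176.616	588.812							x	Trp dioxidation
R	pERWPGPKVPPL	1257.710	629.359	x						x
R	pERWPGPKVPPLE	1386.753	693.881	x							identical to ID: A0A1I9KNP8
further	pEKY	421.208		x	x	x	x	x	x	x
further	pEDW	431.156			x
further	pEDWR	587.258			x
further	pELSPR	583.320							x
further	pEHPGGGGGGW	892.370	446.688			x	x	x		x	pHpG-related
further	pERRPPEIPP	1072.590	536.799	x		x	x
further	WPGPKVPP	877.493	439.250	x						x
further	pEMWPGPKVPP	1119.566	560.287	x
NP	DNEPP	571.236			x
NP	DNEPPKKVPPN	1234.643	617.825	x
NP	EDNEPP	700.278	350.643							x
NP	EDNEPPKKLPPS	1350.690	675.849							x
NP	IGSVSGLGC_CAM_NK	1091.551	546.279		x	x		x	x		BU tryptic digest, protected Cys
NP	IGSHSGLGC_CAM_NK	1129.542	565.275							x	BU tryptic digest, protected Cys
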