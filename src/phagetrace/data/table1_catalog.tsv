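position	ref	alt	effect	orf	function	G1	G2	G3	G4	color	unassigned	placeholder	closed_A	open_A	closed_B	open_B
1276	T	G	Intergenic	-	-	0	1	0	1	blue	0	0	1	1	0	1
16296	T	A	Leu->Ile	0042	ATP-dependent protease	0	0	0	1	yellow	0	0	0	0	0	1
22232	A	G	Synonymous	0050	DNA polymerase	0	0	0	1	yellow	0	0	0	0	0	1
24224	T	C	Ile->Thr	0051	HNH endonuclease	0	1	1	0	pink	0	0	1	1	0	1
24375	G	A	Synonymous	0051	HNH endonuclease	0	1	1	0	pink	0	0	1	1	0	1
24378	T	C	Synonymous	0051	HNH endonuclease	0	1	1	0	pink	0	0	1	1	0	1
46679	C	T	Gly->Ser	0065	Hypothetical protein	0	0	0	1	yellow	0	0	0	0	0	1
48300	A	G	Unspecified	0068	Major head protein	0	0	0	1	yellow	0	1	0	0	0	1
48700	C	T	Unspecified	0068	Major head protein	0	0	0	1	yellow	0	1	0	0	0	1
49100	G	A	Unspecified	0068	Major head protein	0	0	0	1	yellow	0	1	0	0	0	1
51895	G	T	Leu->Ile	0071	Portal protein	0	0	0	1	yellow	0	0	0	0	0	1
54689	T	C	Glu->Gly	0076	Endolysin	0	1	0	0	green	0	0	1	1	0	1
54853	T	C	Synonymous	0076	Endolysin	0	1	0	0	green	0	0	1	1	0	1
54856	C	T	Synonymous	0076	Endolysin	0	1	0	0	green	0	0	1	1	0	1
55030	A	G	Unspecified	0077	Tail fiber protein	0	0	0	1	yellow	0	1	0	0	0	1
55130	C	T	Unspecified	0077	Tail fiber protein	0	0	0	1	yellow	0	1	0	0	0	1
55230	G	A	Unspecified	0077	Tail fiber protein	0	0	0	1	yellow	0	1	0	0	0	1
55320	A	C	Val->Gly	0077	Tail fiber protein	0	1	0	0	green	0	0	1	1	0	1
55330	T	C	Unspecified	0077	Tail fiber protein	0	0	0	1	yellow	0	1	0	0	0	1
55430	A	G	Unspecified	0077	Tail fiber protein	0	0	0	1	yellow	0	1	0	0	0	1
55530	C	T	Unspecified	0077	Tail fiber protein	0	0	0	1	yellow	0	1	0	0	0	1
55630	G	A	Unspecified	0077	Tail fiber protein	0	0	0	1	yellow	0	1	0	0	0	1
55730	T	C	Unspecified	0077	Tail fiber protein	0	0	0	1	yellow	0	1	0	0	0	1
55814	C	T	Synonymous	0077	Tail fiber protein	0	1	0	1	blue	0	0	1	1	0	1
55830	A	G	Unspecified	0077	Tail fiber protein	0	0	0	1	gray	1	1	1	1	0	0
55930	C	T	Unspecified	0077	Tail fiber protein	0	0	0	1	gray	1	1	1	1	0	0
56030	G	A	Unspecified	0077	Tail fiber protein	0	0	0	1	gray	1	1	1	1	0	0
56130	T	C	Unspecified	0077	Tail fiber protein	0	0	0	1	gray	1	1	1	1	0	0
56230	A	G	Unspecified	0077	Tail fiber protein	0	0	0	1	gray	1	1	1	1	0	0
56330	C	T	Unspecified	0077	Tail fiber protein	0	0	0	1	gray	1	1	1	1	0	0
57150	A	G	Unspecified	0080	Hypothetical protein	0	0	0	1	yellow	0	1	0	0	0	1
57250	C	T	Unspecified	0080	Hypothetical protein	0	0	0	1	yellow	0	1	0	0	0	1
57350	G	A	Unspecified	0080	Hypothetical protein	0	0	0	1	yellow	0	1	0	0	0	1
57450	T	C	Unspecified	0080	Hypothetical protein	0	0	0	1	yellow	0	1	0	0	0	1
57550	A	G	Unspecified	0080	Hypothetical protein	0	0	0	1	yellow	0	1	0	0	0	1
57650	C	T	Unspecified	0080	Hypothetical protein	0	0	0	1	yellow	0	1	0	0	0	1
57750	G	A	Unspecified	0080	Hypothetical protein	0	0	0	1	yellow	0	1	0	0	0	1
57850	T	C	Unspecified	0080	Hypothetical protein	0	0	0	1	yellow	0	1	0	0	0	1
57950	A	G	Unspecified	0080	Hypothetical protein	0	0	0	1	yellow	0	1	0	0	0	1
58050	C	T	Unspecified	0080	Hypothetical protein	0	0	0	1	yellow	0	1	0	0	0	1
58150	G	A	Unspecified	0080	Hypothetical protein	0	0	0	1	yellow	0	1	0	0	0	1
58250	T	C	Unspecified	0080	Hypothetical protein	0	0	0	1	yellow	0	1	0	0	0	1
58350	A	G	Unspecified	0080	Hypothetical protein	0	0	0	1	yellow	0	1	0	0	0	1
58450	C	T	Unspecified	0080	Hypothetical protein	0	0	0	1	yellow	0	1	0	0	0	1
58650	A	G	Intergenic	-	-	0	0	0	1	yellow	0	1	0	0	0	1
58680	C	T	Intergenic	-	-	0	0	0	1	yellow	0	1	0	0	0	1
58800	A	G	Unspecified	0081	Head decoration	0	0	0	1	yellow	0	1	0	0	0	1
58890	C	T	Unspecified	0081	Head decoration	0	0	0	1	yellow	0	1	0	0	0	1
58980	G	A	Unspecified	0081	Head decoration	0	0	0	1	yellow	0	1	0	0	0	1
59070	T	C	Unspecified	0081	Head decoration	0	0	0	1	yellow	0	1	0	0	0	1
59160	A	G	Unspecified	0081	Head decoration	0	0	0	1	yellow	0	1	0	0	0	1
59250	C	T	Unspecified	0081	Head decoration	0	0	0	1	yellow	0	1	0	0	0	1
59340	G	A	Unspecified	0081	Head decoration	0	0	0	1	yellow	0	1	0	0	0	1
59430	T	C	Unspecified	0081	Head decoration	0	0	0	1	yellow	0	1	0	0	0	1
59520	A	G	Unspecified	0081	Head decoration	0	0	0	1	yellow	0	1	0	0	0	1
59610	C	T	Unspecified	0081	Head decoration	0	0	0	1	yellow	0	1	0	0	0	1
59700	G	A	Unspecified	0081	Head decoration	0	0	0	1	yellow	0	1	0	0	0	1
59790	T	C	Unspecified	0081	Head decoration	0	0	0	1	yellow	0	1	0	0	0	1
59880	A	G	Unspecified	0081	Head decoration	0	0	0	1	yellow	0	1	0	0	0	1
59970	C	T	Unspecified	0081	Head decoration	0	0	0	1	yellow	0	1	0	0	0	1
60060	G	A	Unspecified	0081	Head decoration	0	0	0	1	yellow	0	1	0	0	0	1
60150	T	C	Unspecified	0081	Head decoration	0	0	0	1	yellow	0	1	0	0	0	1
60240	A	G	Unspecified	0081	Head decoration	0	0	0	1	yellow	0	1	0	0	0	1
60330	C	T	Unspecified	0081	Head decoration	0	0	0	1	yellow	0	1	0	0	0	1
60420	G	A	Unspecified	0081	Head decoration	0	0	0	1	yellow	0	1	0	0	0	1
60510	T	C	Unspecified	0081	Head decoration	0	0	0	1	yellow	0	1	0	0	0	1
60600	A	G	Unspecified	0081	Head decoration	0	0	0	1	yellow	0	1	0	0	0	1
60690	C	T	Unspecified	0081	Head decoration	0	0	0	1	yellow	0	1	0	0	0	1
60850	A	G	Unspecified	0082	L-shaped tail fiber protein assembly	0	0	0	1	yellow	0	1	0	0	0	1
61050	C	T	Unspecified	0082	L-shaped tail fiber protein assembly	0	0	0	1	yellow	0	1	0	0	0	1
61250	G	A	Unspecified	0082	L-shaped tail fiber protein assembly	0	0	0	1	yellow	0	1	0	0	0	1
61450	T	C	Unspecified	0082	L-shaped tail fiber protein assembly	0	0	0	1	yellow	0	1	0	0	0	1
61650	A	G	Unspecified	0082	L-shaped tail fiber protein assembly	0	0	0	1	yellow	0	1	0	0	0	1
61850	C	T	Unspecified	0082	L-shaped tail fiber protein assembly	0	0	0	1	yellow	0	1	0	0	0	1
62050	G	A	Unspecified	0082	L-shaped tail fiber protein assembly	0	0	0	1	yellow	0	1	0	0	0	1
62250	T	C	Unspecified	0082	L-shaped tail fiber protein assembly	0	0	0	1	yellow	0	1	0	0	0	1
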