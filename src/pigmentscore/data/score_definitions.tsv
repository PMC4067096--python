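score	gene	rsid	chromosome	position	major	minor	risk
skin_colour	IRF4	rs12203592	6p25.3	341321	C	T	T
skin_colour	TYR	rs1042602	11q14.3	88551344	C	A	A
skin_colour	HERC2	rs12913832	15q13.1	26039213	G	A	G
skin_colour	MC1R	rs1805007	16q24.3	88513618	C	T	T
skin_colour	ASIP	rs4911414	20q11.22	32193105	G	T	T
skin_colour	ASIP	rs1015362	20q11.22	32202273	G	A	G
tanning	PPARGC1B	rs32579	5q32	149191041	G	A	G
tanning	IRF4	rs12203592	6p25.3	341321	C	T	T
tanning	IRF4/EXOC2	rs12210050	6p25.3	420489	C	T	T
tanning	TYR	rs1393350	11q14.3	88650694	G	A	A
tanning	CALCOCO1/HOXC13	rs7969151	12q13.13	52445544	G	A	A
tanning	PAPOLA/VRK1	rs17094273	14q32.2	96173560	G	A	A
tanning	HERC2	rs12913832	15q13.1	26039213	G	A	G
tanning	CPNE7/DPEP1	rs154659	16q24.3	88194838	T	C	C
tanning	MC1R	rs1805007	16q24.3	88513618	C	T	T
tanning	DBNDD1	rs11648785	16q24.3	88612062	C	T	C
tanning	ASIP	rs4911414	20q11.22	32193105	G	T	T
tanning	ASIP	rs1015362	20q11.22	32202273	G	A	G
tanning	PRDM15	rs7279297	21q22.3	42100984	A	G	A
freckling	IRF4	rs12203592	6p25.3	341321	C	T	T
freckling	BNC2	rs2153271	9p22.2	16854521	A	G	A
freckling	TYR	rs1042602	11q14.3	88551344	C	A	C
freckling	TYR	rs1393350	11q14.3	88650694	G	A	A
freckling	MC1R	rs1805007	16q24.3	88513618	C	T	T
freckling	ASIP	rs4911414	20q11.22	32193105	G	T	T
freckling	ASIP	rs1015362	20q11.22	32202273	G	A	G
freckling	EIF6	rs619865	20q11.22	33331111	G	A	A
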