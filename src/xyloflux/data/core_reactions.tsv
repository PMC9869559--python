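id	equation	lb	ub	gene_rule	subsystem
EX_xyl__D_e	1 xyl__D_e <->	-1000	1000		EXCHANGE
EX_co2_e	1 co2_e <->	-1000	1000		EXCHANGE
EX_o2_e	1 o2_e <->	-1000	1000		EXCHANGE
EX_h2o_e	1 h2o_e <->	-1000	1000		EXCHANGE
EX_h_e	1 h_e <->	-1000	1000		EXCHANGE
EX_pi_e	1 pi_e <->	-1000	1000		EXCHANGE
EX_btol_e	1 btol_e ->	0	1000		EXCHANGE
EX_glyclt_e	1 glyclt_e ->	0	1000		EXCHANGE
XYLt	1 xyl__D_e -> 1 xyl__D_c	0	1000	xtr1 or xtr2	TRANSPORT
CO2t	1 co2_c <-> 1 co2_e	-1000	1000		TRANSPORT
O2t	1 o2_e <-> 1 o2_c	-1000	1000		TRANSPORT
H2Ot	1 h2o_c <-> 1 h2o_e	-1000	1000		TRANSPORT
Ht	1 h_c <-> 1 h_e	-1000	1000		TRANSPORT
PIt	1 pi_e <-> 1 pi_c	-1000	1000	pho84	TRANSPORT
BTOLt	1 btol_c -> 1 btol_e	0	1000		TRANSPORT
GLYCLTt	1 glyclt_c -> 1 glyclt_e	0	1000		TRANSPORT
XYLR	1 xyl__D_c + 1 nadph_c + 1 h_c -> 1 xylt_c + 1 nadp_c	0	1000	Mtxyl1	OXORED
XYLTD	1 xylt_c + 1 nad_c -> 1 xylu__D_c + 1 nadh_c + 1 h_c	0	1000	xdh1	OXORED
XYLK	1 xylu__D_c + 1 atp_c -> 1 xu5p__D_c + 1 adp_c + 1 h_c	0	1000	xks1	OXORED
XYLI	1 xyl__D_c -> 1 xylu__D_c	0	1000	xylA_Ec	ISOMERASE
XDH1	1 xyl__D_c + 1 nadp_c -> 1 xylnl_c + 1 nadph_c + 1 h_c	0	1000	Mtxyd1	WEIMBERG
XYLLACT	1 xylnl_c + 1 h2o_c -> 1 xyln_c + 1 h_c	0	1000		WEIMBERG
XYLLACT2	1 xylnl_c + 1 h2o_c -> 1 xyln_c + 1 h_c	0	0	xylC	WEIMBERG
XYLNDH	1 xyln_c -> 1 kdx_c + 1 h2o_c	0	1000	xylD	WEIMBERG
KDXD	1 kdx_c -> 1 akgsa_c + 1 h2o_c	0	1000	xylX or BxxylX	WEIMBERG
KGSADH	1 akgsa_c + 1 nad_c + 1 h2o_c -> 1 akg_c + 1 nadh_c	0	1000	xylA or ksaD	WEIMBERG
KDXA	1 kdx_c -> 1 pyr_c + 1 gcald_c	0	1000	yagE	DAHMS
GCALDD	1 gcald_c + 1 nad_c + 1 h2o_c -> 1 glyclt_c + 1 nadh_c + 2 h_c	0	1000	aldA	DAHMS
KDXDC	1 kdx_c + 1 h_c -> 1 dhbal_c + 1 co2_c	0	1000	mdlC or kivD	BT
BTOLDH	1 dhbal_c + 1 nadh_c + 1 h_c -> 1 btol_c + 1 nad_c	0	1000	adh1	BT
PGI	1 g6p_c <-> 1 f6p_c	-1000	1000	pgi1	EMP
PFK	1 f6p_c + 1 atp_c -> 1 fdp_c + 1 adp_c + 1 h_c	0	1000	pfk1	EMP
FBP	1 fdp_c + 1 h2o_c -> 1 f6p_c + 1 pi_c	0	1000	fbp1	EMP
FBA	1 fdp_c <-> 1 dhap_c + 1 g3p_c	-1000	1000	fba1	EMP
TPI	1 dhap_c <-> 1 g3p_c	-1000	1000	tpi1	EMP
GAPD	1 g3p_c + 1 nad_c + 1 pi_c <-> 1 13dpg_c + 1 nadh_c + 1 h_c	-1000	1000	tdh1	EMP
PGK	1 13dpg_c + 1 adp_c <-> 1 3pg_c + 1 atp_c	-1000	1000	pgk1	EMP
PGM	1 3pg_c <-> 1 2pg_c	-1000	1000	gpm1	EMP
ENO	1 2pg_c <-> 1 pep_c + 1 h2o_c	-1000	1000	eno1	EMP
PYK	1 pep_c + 1 adp_c + 1 h_c -> 1 pyr_c + 1 atp_c	0	1000	pyk1	EMP
PDH	1 pyr_c + 1 coa_c + 1 nad_c -> 1 accoa_c + 1 co2_c + 1 nadh_c	0	1000	pda1 and pdb1 and lpd1	EMP
PEPCK	1 oaa_c + 1 atp_c -> 1 pep_c + 1 adp_c + 1 co2_c	0	1000	pck1	EMP
G6PDH	1 g6p_c + 1 nadp_c -> 1 6pgl_c + 1 nadph_c + 1 h_c	0	1000	zwf1	PPP
PGL	1 6pgl_c + 1 h2o_c -> 1 6pgc_c + 1 h_c	0	1000	sol1	PPP
GND	1 6pgc_c + 1 nadp_c -> 1 ru5p__D_c + 1 co2_c + 1 nadph_c	0	1000	gnd1	PPP
RPE	1 ru5p__D_c <-> 1 xu5p__D_c	-1000	1000	rpe1	PPP
RPI	1 r5p_c <-> 1 ru5p__D_c	-1000	1000	rki1	PPP
TKT1	1 xu5p__D_c + 1 r5p_c <-> 1 s7p_c + 1 g3p_c	-1000	1000	tkl1 or tkl2	PPP
TALA	1 s7p_c + 1 g3p_c <-> 1 e4p_c + 1 f6p_c	-1000	1000	tal1	PPP
TKT2	1 xu5p__D_c + 1 e4p_c <-> 1 f6p_c + 1 g3p_c	-1000	1000	tkl1 or tkl2	PPP
CS	1 accoa_c + 1 oaa_c + 1 h2o_c -> 1 cit_c + 1 coa_c + 1 h_c	0	1000	cit1	TCA
ACONT	1 cit_c <-> 1 icit_c	-1000	1000	aco1	TCA
ICDH	1 icit_c + 1 nad_c + 2 h_c -> 1 akg_c + 1 co2_c + 1 nadh_c	0	1000	idh1 and idh2	TCA
AKGDH	1 akg_c + 1 coa_c + 1 nad_c -> 1 succoa_c + 1 co2_c + 1 nadh_c + 2 h_c	0	1000	kgd1 and kgd2 and lpd1	TCA
SUCOAS	1 succoa_c + 1 adp_c + 1 pi_c <-> 1 succ_c + 1 atp_c + 1 coa_c	-1000	1000	lsc1 and lsc2	TCA
SUCD	1 succ_c + 1 fad_c -> 1 fum_c + 1 fadh2_c	0	1000	sdh1 and sdh2	TCA
FUM	1 fum_c + 1 h2o_c <-> 1 mal__L_c	-1000	1000	fum1	TCA
MDH	1 mal__L_c + 1 nad_c <-> 1 oaa_c + 1 nadh_c + 1 h_c	-1000	1000	mdh1	TCA
PC	1 pyr_c + 1 atp_c + 1 co2_c + 1 h2o_c -> 1 oaa_c + 1 adp_c + 1 pi_c + 2 h_c	0	1000	Aopyc	TCA
NADHOR	1 nadh_c + 3.5 h_c + 0.5 o2_c + 2.5 adp_c + 2.5 pi_c -> 1 nad_c + 3.5 h2o_c + 2.5 atp_c	0	1000	ndi1	OXPHOS
FADHOR	1 fadh2_c + 1.5 h_c + 0.5 o2_c + 1.5 adp_c + 1.5 pi_c -> 1 fad_c + 2.5 h2o_c + 1.5 atp_c	0	1000	etf1	OXPHOS
THD	1 nadph_c + 1 nad_c <-> 1 nadp_c + 1 nadh_c	-1000	1000		OXPHOS
ATPM	1 atp_c + 1 h2o_c -> 1 adp_c + 1 pi_c + 1 h_c	0	1000		OXPHOS
BIOMASS	1.8 g6p_c + 0.65 f6p_c + 0.7 r5p_c + 0.25 e4p_c + 0.1 g3p_c + 0.9 3pg_c + 0.25 pep_c + 1.75 pyr_c + 2.05 accoa_c + 1.3 oaa_c + 1.1 akg_c + 11 nadph_c + 2.5 nad_c + 40 atp_c + 40 h2o_c -> 2.05 coa_c + 11 nadp_c + 2.5 nadh_c + 40 adp_c + 40 pi_c + 40 h_c	0	1000		BIOMASS
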