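#! meta: model_hash=1014ceade19c03a8
#! meta: name=ccm_core
#! meta: organism=Escherichia coli (core model)
#! metabolites: 13dpg_c 2pg_c 3pg_c 6pgc_c 6pgl_c ac_c ac_e acald_c acald_e accoa_c actp_c adp_c akg_c akg_e amp_c atp_c cit_c co2_c co2_e coa_c dhap_c e4p_c f6p_c fdp_c for_c for_e fru_e fum_c fum_e g3p_c g6p_c glc__D_e gln__L_c gln__L_e glu__L_c glu__L_e glx_c h2o_c h2o_e h_c h_e icit_c lac__D_c lac__D_e mal__L_c mal__L_e nad_c nadh_c nadp_c nadph_c nh4_c nh4_e o2_c o2_e oaa_c pep_c pi_c pi_e pyr_c pyr_e q8_c q8h2_c r5p_c ru5p__D_c s7p_c succ_c succ_e succoa_c xu5p__D_c
#! precursors: 3pg_c accoa_c e4p_c f6p_c g3p_c g6p_c gln__L_c glu__L_c oaa_c pep_c pyr_c r5p_c
#! cofactor_pair: ME1 ME2
#! cofactor_pair: NADTRHD THD2
#! cofactor_pair: ATPS4 ATPase
id	equation	reversible	lb	ub	class
ACALD	acald_c + coa_c + nad_c <-> accoa_c + h_c + nadh_c	1	-1000.0	1000.0	internal
ACALDt	acald_e <-> acald_c	1	-1000.0	1000.0	transport
ACKr	ac_c + atp_c <-> actp_c + adp_c	1	-1000.0	1000.0	internal
ACt2r	ac_e + h_e <-> ac_c + h_c	1	-1000.0	1000.0	transport
ADK1	amp_c + atp_c <-> 2 adp_c	1	-1000.0	1000.0	internal
AKGDH	akg_c + coa_c + nad_c -> co2_c + nadh_c + succoa_c	0	0.0	1000.0	internal
AKGt2r	akg_e + h_e <-> akg_c + h_c	1	-1000.0	1000.0	transport
Biomass_Ecoli_core	1.496 3pg_c + 3.7478 accoa_c + 59.81 atp_c + 0.361 e4p_c + 0.0709 f6p_c + 0.129 g3p_c + 0.205 g6p_c + 0.2557 gln__L_c + 4.9414 glu__L_c + 59.81 h2o_c + 3.547 nad_c + 13.0279 nadph_c + 1.7867 oaa_c + 0.5191 pep_c + 2.8328 pyr_c + 0.8977 r5p_c -> 59.81 adp_c + 4.1182 akg_c + 3.7478 coa_c + 59.81 h_c + 3.547 nadh_c + 13.0279 nadp_c + 59.81 pi_c	0	0.0	1000.0	biomass
CO2t	co2_e <-> co2_c	1	-1000.0	1000.0	transport
CS	accoa_c + h2o_c + oaa_c -> cit_c + coa_c + h_c	0	0.0	1000.0	internal
CYTBD	2 h_c + 0.5 o2_c + q8h2_c -> h2o_c + 2 h_e + q8_c	0	0.0	1000.0	internal
D_LACt2	h_e + lac__D_e <-> h_c + lac__D_c	1	-1000.0	1000.0	transport
ENO	2pg_c <-> h2o_c + pep_c	1	-1000.0	1000.0	internal
EX_ac_e	ac_e ->	0	0.0	1000.0	exchange
EX_acald_e	acald_e ->	0	0.0	1000.0	exchange
EX_akg_e	akg_e ->	0	0.0	1000.0	exchange
EX_co2_e	co2_e <->	1	-1000.0	1000.0	exchange
EX_for_e	for_e ->	0	0.0	1000.0	exchange
EX_fru_e	fru_e ->	0	0.0	1000.0	exchange
EX_fum_e	fum_e ->	0	0.0	1000.0	exchange
EX_glc__D_e	glc__D_e <->	1	-10.0	1000.0	exchange
EX_gln__L_e	gln__L_e ->	0	0.0	1000.0	exchange
EX_glu__L_e	glu__L_e ->	0	0.0	1000.0	exchange
EX_h_e	h_e <->	1	-1000.0	1000.0	exchange
EX_h2o_e	h2o_e <->	1	-1000.0	1000.0	exchange
EX_lac__D_e	lac__D_e ->	0	0.0	1000.0	exchange
EX_mal__L_e	mal__L_e ->	0	0.0	1000.0	exchange
EX_nh4_e	nh4_e <->	1	-1000.0	1000.0	exchange
EX_o2_e	o2_e <->	1	-1000.0	1000.0	exchange
EX_pi_e	pi_e <->	1	-1000.0	1000.0	exchange
EX_pyr_e	pyr_e ->	0	0.0	1000.0	exchange
EX_succ_e	succ_e ->	0	0.0	1000.0	exchange
FBA	fdp_c <-> dhap_c + g3p_c	1	-1000.0	1000.0	internal
FBP	fdp_c + h2o_c -> f6p_c + pi_c	0	0.0	1000.0	internal
FORt2	for_e + h_e -> for_c + h_c	0	0.0	1000.0	transport
FORti	for_c -> for_e	0	0.0	1000.0	transport
FRD7	fum_c + q8h2_c -> q8_c + succ_c	0	0.0	1000.0	internal
FRUpts2	fru_e + pep_c -> f6p_c + pyr_c	0	0.0	1000.0	transport
FUM	fum_c + h2o_c <-> mal__L_c	1	-1000.0	1000.0	internal
FUMt2_2	fum_e + 2 h_e -> fum_c + 2 h_c	0	0.0	1000.0	transport
G6PDH2r	g6p_c + nadp_c <-> 6pgl_c + h_c + nadph_c	1	-1000.0	1000.0	internal
GAPD	g3p_c + nad_c + pi_c <-> 13dpg_c + h_c + nadh_c	1	-1000.0	1000.0	internal
GLCpts	glc__D_e + pep_c -> g6p_c + pyr_c	0	0.0	1000.0	transport
GLNS	atp_c + glu__L_c + nh4_c -> adp_c + gln__L_c + h_c + pi_c	0	0.0	1000.0	internal
GLNabc	atp_c + gln__L_e + h2o_c -> adp_c + gln__L_c + h_c + pi_c	0	0.0	1000.0	transport
GLUDy	glu__L_c + h2o_c + nadp_c <-> akg_c + h_c + nadph_c + nh4_c	1	-1000.0	1000.0	internal
GLUN	gln__L_c + h2o_c -> glu__L_c + nh4_c	0	0.0	1000.0	internal
GLUSy	akg_c + gln__L_c + h_c + nadph_c -> 2 glu__L_c + nadp_c	0	0.0	1000.0	internal
GLUt2r	glu__L_e + h_e <-> glu__L_c + h_c	1	-1000.0	1000.0	transport
GND	6pgc_c + nadp_c -> co2_c + nadph_c + ru5p__D_c	0	0.0	1000.0	internal
H2Ot	h2o_e <-> h2o_c	1	-1000.0	1000.0	transport
ICDHyr	icit_c + nadp_c <-> akg_c + co2_c + nadph_c	1	-1000.0	1000.0	internal
ICL	icit_c -> glx_c + succ_c	0	0.0	1000.0	internal
LDH_D	lac__D_c + nad_c <-> h_c + nadh_c + pyr_c	1	-1000.0	1000.0	internal
MALS	accoa_c + glx_c + h2o_c -> coa_c + h_c + mal__L_c	0	0.0	1000.0	internal
MALt2_2	2 h_e + mal__L_e -> 2 h_c + mal__L_c	0	0.0	1000.0	transport
MDH	mal__L_c + nad_c <-> h_c + nadh_c + oaa_c	1	-1000.0	1000.0	internal
ME1	mal__L_c + nad_c -> co2_c + nadh_c + pyr_c	0	0.0	1000.0	internal
ME2	mal__L_c + nadp_c -> co2_c + nadph_c + pyr_c	0	0.0	1000.0	internal
NADH16	4 h_c + nadh_c + q8_c -> 3 h_e + nad_c + q8h2_c	0	0.0	1000.0	internal
NADTRHD	nad_c + nadph_c -> nadh_c + nadp_c	0	0.0	1000.0	internal
NH4t	nh4_e <-> nh4_c	1	-1000.0	1000.0	transport
O2t	o2_e <-> o2_c	1	-1000.0	1000.0	transport
PDH	coa_c + nad_c + pyr_c -> accoa_c + co2_c + nadh_c	0	0.0	1000.0	internal
PFK	atp_c + f6p_c -> adp_c + fdp_c + h_c	0	0.0	1000.0	internal
PFL	coa_c + pyr_c -> accoa_c + for_c	0	0.0	1000.0	internal
PGI	g6p_c <-> f6p_c	1	-1000.0	1000.0	internal
PGK	3pg_c + atp_c <-> 13dpg_c + adp_c	1	-1000.0	1000.0	internal
PGL	6pgl_c + h2o_c -> 6pgc_c + h_c	0	0.0	1000.0	internal
PGM	2pg_c <-> 3pg_c	1	-1000.0	1000.0	internal
PIt2r	h_e + pi_e <-> h_c + pi_c	1	-1000.0	1000.0	transport
PPC	co2_c + h2o_c + pep_c -> h_c + oaa_c + pi_c	0	0.0	1000.0	internal
PPCK	atp_c + oaa_c -> adp_c + co2_c + pep_c	0	0.0	1000.0	internal
PPS	atp_c + h2o_c + pyr_c -> amp_c + 2 h_c + pep_c + pi_c	0	0.0	1000.0	internal
PTAr	accoa_c + pi_c <-> actp_c + coa_c	1	-1000.0	1000.0	internal
PYK	adp_c + h_c + pep_c -> atp_c + pyr_c	0	0.0	1000.0	internal
PYRt2	h_e + pyr_e <-> h_c + pyr_c	1	-1000.0	1000.0	transport
RPE	ru5p__D_c <-> xu5p__D_c	1	-1000.0	1000.0	internal
RPI	r5p_c <-> ru5p__D_c	1	-1000.0	1000.0	internal
SUCCt2_2	2 h_e + succ_e -> 2 h_c + succ_c	0	0.0	1000.0	transport
SUCCt3	h_e + succ_c -> h_c + succ_e	0	0.0	1000.0	transport
SUCDi	q8_c + succ_c -> fum_c + q8h2_c	0	0.0	1000.0	internal
SUCOAS	atp_c + coa_c + succ_c <-> adp_c + pi_c + succoa_c	1	-1000.0	1000.0	internal
TALA	g3p_c + s7p_c <-> e4p_c + f6p_c	1	-1000.0	1000.0	internal
THD2	2 h_e + nadh_c + nadp_c -> 2 h_c + nad_c + nadph_c	0	0.0	1000.0	internal
TKT1	r5p_c + xu5p__D_c <-> g3p_c + s7p_c	1	-1000.0	1000.0	internal
TKT2	e4p_c + xu5p__D_c <-> f6p_c + g3p_c	1	-1000.0	1000.0	internal
TPI	dhap_c <-> g3p_c	1	-1000.0	1000.0	internal
ACONT	cit_c <-> icit_c	1	-1000.0	1000.0	internal
ATPS4	adp_c + 4 h_e + pi_c -> atp_c + h2o_c + 3 h_c	0	0.0	1000.0	internal
ATPase	atp_c + h2o_c + 3 h_c -> adp_c + 4 h_e + pi_c	0	0.0	1000.0	internal
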