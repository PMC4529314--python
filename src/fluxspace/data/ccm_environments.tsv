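environment	exchange	bound	role
glucose	EX_glc__D_e	10.0	carbon
glucose	EX_co2_e	1000.0	shared
glucose	EX_h_e	1000.0	shared
glucose	EX_h2o_e	1000.0	shared
glucose	EX_nh4_e	1000.0	shared
glucose	EX_o2_e	1000.0	shared
glucose	EX_pi_e	1000.0	shared
fructose	EX_fru_e	10.0	carbon
fructose	EX_co2_e	1000.0	shared
fructose	EX_h_e	1000.0	shared
fructose	EX_h2o_e	1000.0	shared
fructose	EX_nh4_e	1000.0	shared
fructose	EX_o2_e	1000.0	shared
fructose	EX_pi_e	1000.0	shared
acetate	EX_ac_e	10.0	carbon
acetate	EX_co2_e	1000.0	shared
acetate	EX_h_e	1000.0	shared
acetate	EX_h2o_e	1000.0	shared
acetate	EX_nh4_e	1000.0	shared
acetate	EX_o2_e	1000.0	shared
acetate	EX_pi_e	1000.0	shared
2-oxoglutarate	EX_akg_e	10.0	carbon
2-oxoglutarate	EX_co2_e	1000.0	shared
2-oxoglutarate	EX_h_e	1000.0	shared
2-oxoglutarate	EX_h2o_e	1000.0	shared
2-oxoglutarate	EX_nh4_e	1000.0	shared
2-oxoglutarate	EX_o2_e	1000.0	shared
2-oxoglutarate	EX_pi_e	1000.0	shared
fumarate	EX_fum_e	10.0	carbon
fumarate	EX_co2_e	1000.0	shared
fumarate	EX_h_e	1000.0	shared
fumarate	EX_h2o_e	1000.0	shared
fumarate	EX_nh4_e	1000.0	shared
fumarate	EX_o2_e	1000.0	shared
fumarate	EX_pi_e	1000.0	shared
glutamate	EX_glu__L_e	10.0	carbon
glutamate	EX_co2_e	1000.0	shared
glutamate	EX_h_e	1000.0	shared
glutamate	EX_h2o_e	1000.0	shared
glutamate	EX_nh4_e	1000.0	shared
glutamate	EX_o2_e	1000.0	shared
glutamate	EX_pi_e	1000.0	shared
lactate	EX_lac__D_e	10.0	carbon
lactate	EX_co2_e	1000.0	shared
lactate	EX_h_e	1000.0	shared
lactate	EX_h2o_e	1000.0	shared
lactate	EX_nh4_e	1000.0	shared
lactate	EX_o2_e	1000.0	shared
lactate	EX_pi_e	1000.0	shared
malate	EX_mal__L_e	10.0	carbon
malate	EX_co2_e	1000.0	shared
malate	EX_h_e	1000.0	shared
malate	EX_h2o_e	1000.0	shared
malate	EX_nh4_e	1000.0	shared
malate	EX_o2_e	1000.0	shared
malate	EX_pi_e	1000.0	shared
pyruvate	EX_pyr_e	10.0	carbon
pyruvate	EX_co2_e	1000.0	shared
pyruvate	EX_h_e	1000.0	shared
pyruvate	EX_h2o_e	1000.0	shared
pyruvate	EX_nh4_e	1000.0	shared
pyruvate	EX_o2_e	1000.0	shared
pyruvate	EX_pi_e	1000.0	shared
succinate	EX_succ_e	10.0	carbon
succinate	EX_co2_e	1000.0	shared
succinate	EX_h_e	1000.0	shared
succinate	EX_h2o_e	1000.0	shared
succinate	EX_nh4_e	1000.0	shared
succinate	EX_o2_e	1000.0	shared
succinate	EX_pi_e	1000.0	shared
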