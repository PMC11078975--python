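F: 1.0
MTT: 1.44
n_transit: 4
FM: 0.282
CL_PQ: 17.1
V_PQ: 131.0
CL_CPQ: 0.967
V_CPQ: 22.7
CF_PQ: 0.898
CF_CPQ: 1.06
Q: 0.4
PC_PQ: 0.376
PC_CPQ: 0.00889
MTINF: 100.0
MTT_inf: 0.706
n_transit_inf: 2
TM50: 7.6
gestation_months: 9.2
alloCL_exp: 0.75
alloV_exp: 1.0
ref_weight: 51.0
mw_PQ: 259.35
mw_CPQ: 274.32
omega:
  F: 0.024350114920349716
  MTT: 0.041165935365820805
  FM: 0.16317356517707382
  CL_PQ: 0.022544942142668473
  V_PQ: 0.03620077310581595
  CL_CPQ: 0.06886259633484558
  V_CPQ: 0.030848261793265275
  Q: 0.5903439478206204
pi:
  F: 0.041165935365820805
  MTT: 0.279617642169698
sigma:
  PQ:venous: 0.102
  CPQ:venous: 0.0198
  PQ:capillary: 0.057
  CPQ:capillary: 0.0115
  PQ:milk: 0.156
  CPQ:milk: 0.0911
smoking_effect_on_F: 0.0
age_effect_on_V_PQ: 0.0
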