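{
 "meta": {
  "description": "Desk-scale optimized example solution for the self-selected-speed objective, produced by this package's CMA-ES shooting optimizer (lambda=16, mu=8) with a short-horizon-first, survival-shaped training schedule. A partial solution: it completes a 5 s rollout upright but does not walk steadily.",
  "objective_j_total_5s": 10081.3,
  "rng_seed_chain": [
   101,
   900,
   1234
  ],
  "rollout_distance_m": 0.92,
  "rollout_survival_s": 5.0
 },
 "values": {
  "BFSH_C_PS_K": 0.2691257433673403,
  "BFSH_L+_S_K": 1.3068042412370844,
  "BFSH_L+_S_l_o": 0.8598993110066138,
  "BFSH_V+_LP_K": 0.9651508029077759,
  "BFSH_V+_S_K": 0.1365024886855822,
  "GAS_F+_ES_K": 0.9319537025859411,
  "GAS_F+_MS_K": 2.380605754061305,
  "GAS_F+_PS_K": 1.8176087288174465,
  "GMAX_C_LP_K": 0.14206132669981883,
  "GMAX_C_S_K": 0.06690962463065005,
  "GMAX_PD_ES_kp": 3.8743036888753375,
  "GMAX_PD_ES_kv": 0.45894018357327426,
  "GMAX_PD_ES_theta_o": 0.08314766968977311,
  "GMAX_PD_MS_kp": 4.56102778116189,
  "GMAX_PD_MS_kv": 0.24683218294946851,
  "GMAX_PD_MS_theta_o": 0.10327988906806965,
  "GMAX_PD_PS_kp": 5.115603751073674,
  "GMAX_PD_PS_kv": 0.31415954226180953,
  "GMAX_PD_PS_theta_o": 0.19249093126178704,
  "HAMS_L+_LP_K": 2.0841163723349796,
  "HAMS_L+_LP_l_o": 0.6667457468299487,
  "HAMS_L+_S_K": 1.3171526968269287,
  "HAMS_L+_S_l_o": 0.9993462643647297,
  "HAMS_PD_ES_kp": 3.343428683968055,
  "HAMS_PD_ES_kv": 0.0707355123255275,
  "HAMS_PD_ES_theta_o": 0.07143138545675716,
  "HAMS_PD_MS_kp": 1.5659472281468778,
  "HAMS_PD_MS_kv": 0.3521858772580753,
  "HAMS_PD_MS_theta_o": 0.1408518424119695,
  "HAMS_PD_PS_kp": 1.9481978134183762,
  "HAMS_PD_PS_kv": 0.043058038504817,
  "HAMS_PD_PS_theta_o": -0.05988555235856471,
  "HAMS_V+_LP_K": 0.6485607572431632,
  "ILPSO_C_PS_K": 0.24530809924767083,
  "ILPSO_L+_S_K": 1.778110693410702,
  "ILPSO_L+_S_l_o": 0.6186653029808045,
  "ILPSO_PD_ES_kp": -2.1298648226739787,
  "ILPSO_PD_ES_kv": -0.5287282008594255,
  "ILPSO_PD_ES_theta_o": 0.25088497976381724,
  "ILPSO_PD_MS_kp": -2.5184644024110843,
  "ILPSO_PD_MS_kv": -0.2620892951857989,
  "ILPSO_PD_MS_theta_o": 0.22234721588219428,
  "ILPSO_PD_PS_kp": -0.38503209097334473,
  "ILPSO_PD_PS_kv": -0.5821040725830895,
  "ILPSO_PD_PS_theta_o": 0.29949137380670815,
  "ILPSO_V+_S_K": 0.7226315799981324,
  "RF_F+_ES_K": 0.4286946826873407,
  "RF_L+_S_K": 2.1829165228953116,
  "RF_L+_S_l_o": 1.3819733996702213,
  "SOL_F+_ES_K": 1.0959973274426955,
  "SOL_F+_MS_K": 2.578613368178031,
  "SOL_F+_PS_K": 2.943739403993335,
  "TA_F-_ES_K": 0.22937554278091934,
  "TA_F-_MS_K": 0.8368924552521584,
  "TA_F-_PS_K": 0.23706931905824585,
  "TA_L+_ES_K": 0.6301591005591587,
  "TA_L+_ES_l_o": 0.7244525629397269,
  "TA_L+_LP_K": 0.14104845642682512,
  "TA_L+_LP_l_o": 0.6612412528717919,
  "TA_L+_MS_K": 2.3714633826316622,
  "TA_L+_MS_l_o": 0.44895234619736474,
  "TA_L+_PS_K": 0.5826463414184572,
  "TA_L+_PS_l_o": 0.8428238880052155,
  "TA_L+_S_K": 1.2359738426904032,
  "TA_L+_S_l_o": 0.5322677674960968,
  "VAS_C_ES_K": 0.16442546816862197,
  "VAS_C_LP_K": 0.3782950737397558,
  "VAS_F+_ES_K": 1.1224162250685514,
  "VAS_F+_MS_K": 0.2954160353711989,
  "VAS_F+_PS_K": 0.5038090356021339,
  "init_ankle_l": -0.01981976644689555,
  "init_ankle_l_rate": -1.1417006745701135,
  "init_ankle_r": -0.0012469250764061968,
  "init_ankle_r_rate": 0.16729304848541032,
  "init_hip_l": 0.21960486859516443,
  "init_hip_l_rate": -0.19579537897589938,
  "init_hip_r": -0.057573981945994904,
  "init_hip_r_rate": 1.0009179103925674,
  "init_knee_l": 0.2524690515049888,
  "init_knee_l_rate": 0.48721470756515955,
  "init_knee_r": 0.15732803442657495,
  "init_knee_r_rate": 1.1437145357617526,
  "init_pelvis_tilt": -0.07163085870794778,
  "init_pelvis_tilt_rate": -0.3246924019310553,
  "init_pelvis_vx": 0.88314865623027,
  "init_pelvis_vy": 0.18414584885303786,
  "threshold_es_to_ms_m": 0.13230850831078705,
  "threshold_lp_to_es_n": 50.207724312081474,
  "threshold_ps_to_s_n": 111.30063193577685,
  "threshold_s_to_lp_m": -0.08212207066484334
 }
}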