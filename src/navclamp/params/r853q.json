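{
 "E_gp": 90.0,
 "E_rev": 65.0,
 "V_half_gp": -70.0,
 "V_half_h": -71.5,
 "V_half_m": -33.54282503601717,
 "V_half_q": -30.0,
 "delta_b": 15.0,
 "f_p": 0.0030438992867900068,
 "g_max": 89.33841611784197,
 "genotype": "R853Q",
 "k_gp": 10.0,
 "k_h": 6.0,
 "k_m": 7.0,
 "k_q": 10.0,
 "kb_off0": 0.2,
 "kb_on": 0.23707630830126525,
 "perm_guanidinium": 2.5,
 "s_gp": 0.5656908464090099,
 "schema_version": 1,
 "tau_h0": 0.25,
 "tau_h_Vpeak": -60.0,
 "tau_h_amp": 6.0,
 "tau_h_sigma": 30.0,
 "tau_m0": 0.05,
 "tau_m_Vpeak": -40.0,
 "tau_m_amp": 0.35,
 "tau_m_sigma": 18.0,
 "tau_q": 0.5
}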