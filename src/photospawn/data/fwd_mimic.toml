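[model]
name = "fwd-mimic"
environment = "protein"
kg = [0.085, 0.0584]
le_poly = [3.4737635245546135, -0.9688896811056622, 1.3068115510123937, -0.6111007730900079, 0.08971069443660032]
le_k2 = 0.009
ct_e0 = 1.914863572348875
ct_k1 = 0.07
ct_center = [0.0, 8.066214785811985]
ct_k2 = 0.025117712951033735
ct_wall4 = 0.5
lam = 0.013
eps_env = 1.0
mu_g = 5.0
mu_le = 8.0
mu_ct = 31.0
tdm_le = 1.6
bath_omegas = [0.12, 0.18, 0.24, 0.3, 0.118, 0.151, 0.185, 0.219]
bath_couple = [1, 1, 1, 1, 0, 0, 0, 0]
bath_c = [0.9, 0.9, 0.9, 0.9, 1.2, 1.2, 1.2, 1.2]
bath_ct_shift = [0.7216878364870323, 0.4811252243246882, 0.36084391824351614, 0.2886751345948129, 0.0, 0.0, 0.0, 0.0]
mass_q = [40.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
nac_cap = 1000.0
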