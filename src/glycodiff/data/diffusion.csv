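# Diffusion coefficients (1e-9 m^2/s, 50 mM, 298 K) for 18 carbohydrates:
# DOSY NMR, MD with TIP5P and OPC water, and the empirical hydration-number model
# (R_H from R_g and N = 1.1 N_PA entrained waters, then Stokes-Einstein with
# eta = 0.00089 kg/m.s). Values averaged over both anomers where applicable.
name,d_dosy,d_dosy_sd,d_tip5p,d_tip5p_sd,d_opc,d_opc_sd,d_empirical
Xyl,0.71,0.01,0.79,0.07,0.79,0.05,0.66
Fuc,0.68,0.03,0.76,0.06,0.71,0.03,0.64
Glc,0.63,0.01,0.71,0.03,0.74,0.05,0.61
Gal,0.65,0.02,0.72,0.07,0.73,0.06,0.61
GlcA,0.61,0.01,0.68,0.04,0.67,0.05,0.59
GlcNAc,0.57,0.01,0.67,0.02,0.62,0.03,0.55
GalNAc,0.57,0.01,0.66,0.03,0.63,0.03,0.55
Neu5Ac,0.47,0.01,0.58,0.03,0.50,0.03,0.50
trehalose,0.48,0.01,0.53,0.03,0.47,0.04,0.47
sucrose,0.51,0.02,0.51,0.03,0.51,0.04,0.48
lactose,0.47,0.04,0.48,0.04,0.47,0.03,0.48
maltose,0.46,0.01,0.49,0.03,0.46,0.04,0.48
cellobiose,0.46,0.02,0.48,0.05,0.51,0.04,0.48
Tetra-O-Ac-Glc-a-OMe,0.53,0.02,0.52,0.04,0.46,0.06,0.47
maltotriose,0.40,0.04,0.38,0.03,0.37,0.03,0.41
cellotriose,0.38,0.02,0.38,0.01,0.35,0.03,0.39
maltohexaose,0.27,0.01,0.22,0.01,0.21,0.02,0.27
maltoheptaose,0.24,0.003,0.20,0.01,0.19,0.01,0.25
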