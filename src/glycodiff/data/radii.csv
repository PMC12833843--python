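# Hydrodynamic radii (R_H, Angstrom) and radii of gyration (R_g, Angstrom) for 18 carbohydrates.
# R_H columns: DOSY NMR (eta=0.00089 kg/m.s), TIP5P (eta=0.0007), OPC (eta=0.00079), all at 298 K.
# R_g columns: from simulation in TIP5P and OPC water. *_sd are reported standard deviations.
name,rh_dosy,rh_dosy_sd,rh_tip5p,rh_tip5p_sd,rh_opc,rh_opc_sd,rg_tip5p,rg_tip5p_sd,rg_opc,rg_opc_sd
Xyl,3.46,0.05,3.97,0.34,3.52,0.23,2.34,0.03,2.34,0.04
Fuc,3.64,0.16,4.10,0.33,3.89,0.16,2.54,0.02,2.53,0.02
Glc,3.93,0.06,4.39,0.20,3.74,0.25,2.64,0.04,2.64,0.04
Gal,3.77,0.12,4.36,0.42,3.81,0.32,2.63,0.03,2.62,0.04
GlcA,4.02,0.07,4.59,0.25,4.16,0.31,2.55,0.02,2.55,0.02
GlcNAc,4.30,0.08,4.69,0.18,4.46,0.22,3.24,0.03,3.23,0.04
GalNAc,4.30,0.08,4.76,0.20,4.42,0.21,3.23,0.03,3.22,0.03
Neu5Ac,5.22,0.11,5.38,0.29,5.58,0.34,3.48,0.04,3.47,0.04
trehalose,5.11,0.11,5.89,0.33,5.88,0.50,3.79,0.05,3.80,0.06
sucrose,4.81,0.19,6.12,0.36,5.42,0.43,3.53,0.06,3.53,0.06
lactose,5.22,0.45,6.57,0.56,5.94,0.39,3.84,0.05,3.82,0.05
maltose,5.33,0.12,6.43,0.37,6.01,0.53,3.73,0.05,3.73,0.05
cellobiose,5.33,0.23,6.50,0.69,5.47,0.44,3.85,0.07,3.85,0.05
Tetra-O-Ac-Glc-a-OMe,4.63,0.17,6.00,0.44,6.01,0.80,4.08,0.06,4.08,0.07
maltotriose,6.13,0.62,8.21,0.65,7.47,0.61,4.81,0.09,4.82,0.08
cellotriose,6.54,0.35,8.32,0.22,7.90,0.68,5.22,0.07,5.20,0.08
maltohexaose,9.26,0.17,14.51,0.68,13.16,1.27,7.76,0.27,7.76,0.29
maltoheptaose,10.22,0.11,15.60,0.78,14.94,0.81,8.70,0.38,8.69,0.38
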