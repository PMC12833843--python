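# Experimental hydration numbers (n_H), entrained-water counts (N_W) from the
# volume-difference model, polar-atom counts (N_PA, oxygens) and their ratios,
# for the ten carbohydrates with reported hydration data.
name,n_h,n_w,n_pa,ratio_nh_npa,ratio_nw_npa
Xyl,5.7,4,5,1.14,0.80
Glc,7.41,5.9,6,1.24,0.98
Gal,9.4,4.9,6,1.57,0.82
trehalose,15.3,11,11,1.39,1.00
sucrose,10.9,9.4,11,0.99,0.85
lactose,15.3,12,10,1.53,1.20
maltose,14.5,13.9,10,1.45,1.39
cellobiose,14.8,13.2,10,1.48,1.32
maltotriose,21.3,16.7,16,1.33,1.04
maltohexaose,47.4,45.6,31,1.53,1.47
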