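# Polar-atom (N_PA) bookkeeping for the 18 carbohydrates. Group weights:
# hydroxyl, ring oxygen, glycosidic oxygen and ether each contribute 1 polar
# atom; carboxylate, amide and ester groups contribute 2 each.
# note=printed: N_PA appears in the source hydration table as printed.
# note=derived: N_PA obtained by applying the group-counting rules.
# The disaccharides lactose/maltose/cellobiose are tabulated with N_PA = 10,
# which omits the glycosidic oxygen (trehalose and sucrose count it); the
# group counts below follow that tabulated convention.
name,hydroxyl,ring_oxygen,glycosidic,ether,carboxylate,amide,ester,n_pa,note
Xyl,4,1,0,0,0,0,0,5,printed
Fuc,4,1,0,0,0,0,0,5,derived: 6-deoxy hexose; all oxygens counted
Glc,5,1,0,0,0,0,0,6,printed
Gal,5,1,0,0,0,0,0,6,printed
GlcA,4,1,0,0,1,0,0,7,derived: carboxylate contributes two polar atoms
GlcNAc,4,1,0,0,0,1,0,7,derived: amide contributes two polar atoms
GalNAc,4,1,0,0,0,1,0,7,derived: amide contributes two polar atoms
Neu5Ac,5,1,0,0,1,1,0,10,derived: carboxylate and amide contribute two each
trehalose,8,2,1,0,0,0,0,11,printed
sucrose,8,2,1,0,0,0,0,11,printed
lactose,8,2,0,0,0,0,0,10,printed; glycosidic oxygen omitted in source convention
maltose,8,2,0,0,0,0,0,10,printed; glycosidic oxygen omitted in source convention
cellobiose,8,2,0,0,0,0,0,10,printed; glycosidic oxygen omitted in source convention
Tetra-O-Ac-Glc-a-OMe,0,1,0,1,0,0,4,10,derived: four esters at two each plus ring and methyl ether oxygens
maltotriose,11,3,2,0,0,0,0,16,printed
cellotriose,11,3,2,0,0,0,0,16,derived: all oxygens counted
maltohexaose,20,6,5,0,0,0,0,31,printed
maltoheptaose,23,7,6,0,0,0,0,36,derived: all oxygens counted
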