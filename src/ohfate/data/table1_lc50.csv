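name,pool,molar_mass_g_mol,lc50_mg_L
Bisphenol A,BPA,228.29,3.24
Product A 2-(3 4-dihydroxyphenyl)-2-(4-hydroxyphenyl)acetaldehyde,P_tr,244.24,1.83
Product B 2-(2 4-dihydroxyphenyl)-2-(4-hydroxyphenyl)acetaldehyde,P_tr,244.24,2.26
4-hydroxybenzoic acid,P_or,138.12,92.62
Hydroquinone,P_or,110.11,43.29
4-isopropenylphenol,P_or,140.22,7.67
Benzoic acid,P_or,122.12,101.5
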