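# Tissue composition for Rodgers-Rowland partition-coefficient prediction
# (human values from the published method literature).
# f_ew/f_iw: extracellular/intracellular water volume fractions
# f_nl/f_np: neutral-lipid / neutral-phospholipid volume fractions
# ap_mg_g: acidic phospholipid content (mg/g tissue)
# ra: tissue-to-plasma albumin-type binding-protein ratio
tissue,f_ew,f_iw,f_nl,f_np,ap_mg_g,ra
adipose,0.135,0.017,0.853,0.0016,0.40,0.049
brain,0.162,0.620,0.039,0.0015,0.40,0.048
gut,0.282,0.475,0.038,0.0125,2.41,0.158
heart,0.320,0.456,0.014,0.0111,2.25,0.157
kidney,0.273,0.483,0.012,0.0240,5.03,0.130
liver,0.161,0.573,0.014,0.0240,4.56,0.086
lung,0.336,0.446,0.022,0.0128,3.91,0.212
muscle,0.118,0.630,0.010,0.0072,1.53,0.064
skin,0.382,0.291,0.060,0.0044,1.32,0.277
spleen,0.207,0.579,0.0077,0.0113,3.18,0.097
reproductive,0.280,0.500,0.012,0.0080,1.50,0.100
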