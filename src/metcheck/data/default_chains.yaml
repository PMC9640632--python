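# Chain map: which measured MFA reactions compose each model rate constant.
# A model reaction standing for a chain of measured steps takes the minimum
# (rate-limiting) flux of its members; singleton chains pass through.
# Editable: adjust the membership if the measured reaction set changes.
k_R1: [HK]                  # glucose -> G6P
k_R2: [G6PD]                # G6P -> pentose phosphate pathway
k_R3: [PGI, PFK, GAPD_PK]   # lower glycolysis, lumped chain
k_R4: [LDH]                 # pyruvate -> lactate
k_R5: [PDH]                 # pyruvate -> acetyl-CoA
k_R6: [FASN]                # acetyl-CoA -> lipids
k_R7: [CS]                  # citrate synthase
k_R8: [ACO_IDH]             # citrate -> aKG (aconitase + IDH, one measured step)
k_R9: [AKGDH, SDH, FH]      # oxidative TCA, lumped chain
k_R10: [MDH]                # malate -> oxaloacetate
k_R11: [ME]                 # malic enzyme, malate -> pyruvate
k_R12: [GLS, GDH]           # glutaminolysis, lumped chain
k_2HG: [IDHmut_neo]         # neomorphic aKG -> 2HG (mutant only)
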