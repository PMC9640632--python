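# Glycolysis + TCA-cycle network with the IDH-mutant neomorphic 2HG branch.
# Amounts are discrete molecule counts on the fmol/cell scale; every species
# has a saturation cap beyond which producing reactions are disabled.
#
# Glycolysis / pentose-phosphate / lipid sinks
species Gluc init=5 max=5
species G6P init=0 max=5
species PPP init=0 max=5
species Pyr init=0 max=5
species Lac init=0 max=5
species ACoA init=0 max=5
species Lip init=0 max=5
# Glutaminolysis / TCA cycle
species Gln init=5 max=5
species Cit init=0 max=5
species aKG init=0 max=5
species Mal init=0 max=5
species Oac init=0 max=5
species 2HG init=0 max=5
# Constant indicator of mutant IDH presence: never consumed, only guards R13.
species IDHmut init=0 max=1

R1: Gluc -> G6P @ k_R1          # hexokinase step (ATP-dependence abstracted)
R2: G6P -> PPP @ k_R2           # pentose phosphate pathway (lumped sink)
R3: G6P -> Pyr @ k_R3           # lower glycolysis (lumped chain)
R4: Pyr -> Lac @ k_R4           # lactate dehydrogenase
R5: Pyr -> ACoA @ k_R5          # pyruvate dehydrogenase
R6: ACoA -> Lip @ k_R6          # fatty-acid synthesis (lumped sink)
R7: ACoA + Oac -> Cit @ k_R7    # citrate synthase
R8: Cit -> aKG @ k_R8           # aconitase + IDH (lumped)
R9: aKG -> Mal @ k_R9           # oxidative TCA (lumped chain)
R10: Mal -> Oac @ k_R10         # malate dehydrogenase
R11: Mal -> Pyr @ k_R11         # malic enzyme (TCA -> pyruvate route)
R12: Gln -> aKG @ k_R12         # glutaminolysis (lumped chain)
R13: aKG -> 2HG @ k_2HG | IDHmut > 0   # neomorphic gain of function
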