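# QM interaction energies (ligand vs Asn174/Gly182/Glu184 fragments, kJ/mol),
# COSMO-RS ligand solvation free energy (Solv), and the published Sum column
# (sum of the three interaction energies minus Solv, integer-rounded).
ligand,Solv,dE_Asn174,dE_Gly182,dE_Glu184,Sum
H,-16,-1,-4,-16,-4
F,-10,-6,5,-26,-18
Cl,-13,-6,-3,-24,-21
Br,-14,-6,-6,-26,-25
I,-17,-6,-10,-20,-20
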