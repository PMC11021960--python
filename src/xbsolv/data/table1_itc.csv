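# Global-fit ITC binding thermodynamics for the galectin-3C ligand series at 301 K.
# Kd in uM, energies in kJ/mol; *_err are symmetric standard errors.
ligand,Kd_uM,Kd_err_uM,dH,dH_err,mTdS,mTdS_err,dG,dG_err
H,1.23,0.30,-43.9,2.1,9.8,2.5,-34.1,0.4
F,0.48,0.15,-55.3,2.5,18.8,2.5,-36.4,0.8
Cl,0.22,0.06,-56.6,1.2,18.4,1.7,-38.3,0.8
Br,0.17,0.09,-58.4,3.3,19.4,3.3,-39.0,1.2
I,0.22,0.07,-64.5,2.1,26.2,2.5,-38.3,0.8
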