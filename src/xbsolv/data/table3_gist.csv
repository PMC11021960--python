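# GIST water entropies (-TdS, kJ/mol) from restrained-solute MD of the five
# complexes: whole binding-site grid, the water site(s) seen in each structure,
# and the water site of the Br structure. Errors are standard errors over ten
# independent simulations. The H row's per-structure column sums its two sites.
ligand,mTdS_tot,mTdS_tot_err,mTdS_water,mTdS_water_err,mTdS_water_Br_site,mTdS_water_Br_site_err
H,82.9,0.8,24.2,0.3,12.2,0.2
F,90.6,0.6,12.1,0.1,12.9,0.1
Cl,98.2,0.3,11.3,0.2,13.1,0.2
Br,99.3,0.6,13.0,0.1,13.0,0.1
I,93.3,0.9,13.0,0.3,10.2,0.2
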