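species,phase,N,H,O,charge,dG0f_kJ_mol
NH4+,aq,1,4,0,1,-79.31
NH3(aq),aq,1,3,0,0,-26.50
NH3(g),g,1,3,0,0,-16.45
O2(g),g,0,0,2,0,0.0
NO2-,aq,1,0,2,-1,-32.20
NO3-,aq,1,0,3,-1,-111.30
H2O(l),l,0,2,1,0,-237.18
H+,aq,0,1,0,1,0.0
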