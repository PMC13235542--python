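# Default model constants.
#
# pKa of NH4+ <-> NH3(aq) + H+ at 25 degC; the van't Hoff correction uses the
# standard dissociation enthalpy (52.21 kJ/mol), so colder water holds a
# smaller NH3(aq) fraction at a given pH.
pka_ref: 9.25
dH_dissoc_kJ_mol: 52.21

# Henry solubility constant of NH3 at 25 degC (M/atm) and its van't Hoff
# temperature coefficient -dsolH/R (Kelvin); NH3 is more soluble in cold water.
kh_ref_M_atm: 59.0
kh_vant_hoff_K: 4200.0

# Equilibrium N-isotope enrichment factors (permil) of the volatilization and
# trapping chain. Positive epsilon means the product pool is depleted in 15N.
#   NH4+(aq) -> NH3(aq): 30 permil at 25 degC (32 permil is the commonly cited
#     experimental value; select it by overriding this key).
#   NH3(aq) -> NH3(g): 8.3 permil across the air-water interface.
#   transport: no published magnitude; 0 unless the user supplies one.
#   acid trapping: near-quantitative, hence 0.
eps_nh4_nh3aq_permil: 30.0
eps_nh3aq_nh3g_permil: 8.3
eps_transport_permil: 0.0
eps_trap_permil: 0.0

# "linear" applies delta - eps; "exact" applies (delta+1000)/alpha - 1000.
fractionation_mode: linear

# Two-endmember mixing poles for cave-air / droplet d15N (permil vs air N2):
# stream-air = lowest passive-sampler value just above a degassing stream
# (-27.3; the lowest droplet value -29.0 is an alternative), surface = guano
# near cave entrances (+15).
stream_air_endmember_permil: -27.3
surface_endmember_permil: 15.0
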