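species,epsilon_M_cm,wavelength_nm,surrogate_of
phytoene,68100,286,
phytofluene,73300,348,
zeta-carotene,138200,400,
neurosporene,157300,440,
lycopene,185200,470,
didehydrolycopene,185000,503,
beta-zeacarotene,136300,427,
dihydro-beta-carotene,135000,430,
gamma-carotene,166400,462,
beta-carotene,139200,450,
torulene,173300,484,
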