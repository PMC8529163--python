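ligand_id,gpcr_ligand,ion_channel_modulator,nuclear_receptor_ligand,kinase_inhibitor,protease_inhibitor,enzyme_inhibitor
S-adenosyl homocysteine,1.04,0.44,0.47,-1.18,0.51,1.23
Carbenicillin,0.05,-0.40,-0.75,-0.37,0.85,0.30
Apiin,0.18,-0.17,0.09,0.18,0.17,0.42
Rutine,-0.05,-0.52,-0.14,-0.23,-0.07,0.12
Chloramphenicol monoglucoronide,0.08,-0.06,-0.28,-0.12,0.08,0.28
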