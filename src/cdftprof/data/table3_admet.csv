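ligand_id,caco2,intestinal_absorption,skin_logkp,pgp_substrate,pgp1_inhibitor,pgp2_inhibitor,vdss,fraction_unbound,bbb_logbb,cns_logps,cyp2d6_substrate,cyp3a4_substrate,cyp1a2_inhibitor,cyp2c19_inhibitor,cyp2c9_inhibitor,cyp2d6_inhibitor,cyp3a4_inhibitor,total_clearance,oct2_substrate,ames,max_tolerated_dose,herg1,herg2,orat_ld50,orct,hepatotoxicity,skin_sensitisation,tpyriformis
S-adenosyl homocysteine,-0.506,27.464,-2.735,Yes,Yes,No,-0.575,0.559,-1.630,-4.090,No,No,No,No,No,No,No,0.721,No,No,0.514,No,No,2.403,2.771,Yes,No,0.285
Carbenicillin,0.377,23.953,-2.735,Yes,No,No,-1.804,0.427,-1.051,-3.572,No,No,No,No,No,No,No,0.081,No,No,1.717,No,No,1.856,2.956,Yes,No,0.285
Apiin,0.737,29.350,-2.735,Yes,No,No,-0.108,0.175,-1.523,-5.144,No,No,No,No,No,No,No,0.117,No,No,0.516,No,Yes,2.417,5.414,No,No,0.285
Rutine,-0.763,28.135,-2.735,Yes,No,No,0.013,0.292,-2.080,-5.744,No,No,No,No,No,No,No,-0.200,No,Yes,0.427,No,Yes,2.445,5.414,No,No,0.285
Chloramphenicol monoglucoronide,-0.868,0.000,-2.735,Yes,No,No,-2.144,0.427,-5.744,-4.556,No,No,No,No,No,No,No,0.373,No,No,0.759,No,No,2.439,5.158,No,No,0.285
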