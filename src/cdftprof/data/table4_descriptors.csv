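ligand_id,chi,eta,omega,S,N,omega_minus,omega_plus,net_electrophilicity
S-Adenosylhomocysteine,3.8897,4.2687,1.7722,0.2343,2.7684,5.7561,1.8664,7.6225
Carbenicillin,3.8718,5.6238,1.3328,0.1778,2.1088,4.9530,1.0812,6.0341
Apiin,4.1168,4.6227,1.8332,0.2163,2.3643,6.0136,1.8968,7.9105
Rutine,4.1346,4.1184,2.0754,0.2428,2.5986,6.4756,2.3410,8.8166
Chloramphenicol Monoglucoronide,5.2081,4.2387,3.1996,0.2359,2.8369,9.2682,4.0601,13.3283
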