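protein_id,ligand_id,affinity,n_hbonds,residues
1B8M,S-Adenosylhomocysteine,-6.0,7,THR-83;GLN-84;SER-21;ALA-19;CYS-119
1B8M,Carbenicillin,-7.4,8,THR-59;THR-83;GLN-84;TYR-86;SER-108;THR-117
1B8M,Apiin,-7.2,10,SER-21;ALA-19;GLN-84;SER-108;THR-83;CYS-111;VAL-16;CYS-17
1B8M,Rutine,-6.9,11,SER-17;CYS-13;TYR-54;THR-56;GLN-94;LYS-93;CYS-13;ASP-14
1B8M,Chloramphenicol Monoglucoronide,-7.0,10,GLU-9;SER-11;ASP-14;SER-15;LYS-93;TYR-96
1GS9,S-Adenosylhomocysteine,-5.7,6,GLY-23;GLU-27;ASP-36;ASP-153;GLN-156
1GS9,Carbenicillin,-6.8,3,TRP-34;ASP-35;GLN-156
1GS9,Apiin,-6.0,6,GLU-27;ARG-145;GLN-156
1GS9,Rutine,-6.6,4,VAL-103;SER-104;ARG-108;THR-188;HIS-222;GLU-245;ILE-246
1GS9,Chloramphenicol Monoglucoronide,-6.9,3,GLU-27;ARG-145;GLN-156
3PFQ,S-Adenosylhomocysteine,-6.4,9,VAL-103;SER-104;ARG-108;THR-188;HIS-222;GLU-245;ILE-246
3PFQ,Carbenicillin,-8.6,7,VAL-103;SER-104;ARG-108;PRO-244;GLU-245;ARG-652
3PFQ,Apiin,-9.0,9,SER-104;THR-188;LYS-239;PRO-244;GLU-245;ILE-246;ARG-652
3PFQ,Rutine,-9.5,8,SER-67;SER-102;VAL-103;ARG-108;THR-188;LYS-654;LYS-654;ARG-657;ARG-659
3PFQ,Chloramphenicol Monoglucoronide,-8.6,9,VAL-103;SER-104;ARG-108;GLU-184;HIS-222;ILE-246;ARG-652
5A63,S-Adenosylhomocysteine,-7.7,7,LEU-348;TYR-422;VAL-423;GLY-426;ASP-427;ASP-470
5A63,Carbenicillin,-7.2,2,TYR-422;MET-473
5A63,Apiin,-9.0,8,TYR-123;GLN-128;HIS-140;TYR-422;ASN-424;SER-476
5A63,Rutine,-7.8,8,LEU-348;GLY-351;GLY-354;GLY-426;ASP-427;ASP-470
5A63,Chloramphenicol Monoglucoronide,-7.4,5,TYR-123;GLN-128;GLY-129;LYS-141;SER-476
4L7G,S-Adenosylhomocysteine,-7.8,5,SER-35;ASN-37;TYR-71;ILE-126
4L7G,Carbenicillin,-7.4,5,GLY-11;TYR-71;THR-232
4L7G,Apiin,-7.4,4,GLY-11;SER-35;SER-36;ASN-37;TYR-71;ILE-126;TYR-198;THR-232
4L7G,Rutine,-9.2,8,ASP-32;SER-35;ASN-37;ALA-39;TYR-198;LYS-224;THR-231;ARG-235
4L7G,Chloramphenicol Monoglucoronide,-10.7,10,GLY-11;SER-35;TYR-71;THR-72;GLN-73;GLY-230;THR-232
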