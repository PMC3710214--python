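patient_id,phenotype,gestational_age,allele1,allele2,idua_activity,urt_obstruction,inguinal_hernia
1,H,37 + 0,p.W402X,p.W402X,0.31,-,+
2,H,38 + 1,p.W402X,p.Q70X,X,-,+
3,H,40 + 0,p.W402X,p.Q70X,X,X,X
4,H,39 + 6,p.W402X,p.W402X,0.25,+,-
5,H,37 + 5,p.W402X,c.134del12,0.26,X,-
6,H,33 + 6,p.Q70X,p.L218P,0.47,X,X
7,H,33 + 1,p.Q70X,p.L218P,0.44,X,X
8,H,38 + 0,p.Q70X,p.L218P,0.58,+,X
9,H,37 + 2,p.Q70X,p.L218P,X,+,-
10,H,X,p.W402X,p.L218P,X,+,X
11,H,33 + 0,p.L218P,p.L218P,X,X,X
12,H,40 + 0,p.L218P,p.L218P,X,+,-
13,H,38 + 3,p.W402X,p.L218P,0.43,+,-
14,H,41 + 1,p.A367E,c.1650del117,X,+,+
15,H,38 + 1,c.494-1G>A,c.494-1G>A,0.23,X,+
16,H,X,p.H425fs,p.H425fs,0.32,X,X
17,H,40 + 0,p.W402X,p.W402X,X,X,X
18,HS,40 + 0,p.W402X,p.R505G,0.77,+,-
19,HS,38 + 0,p.W402X,p.N348K,0.92,-,-
20,HS,37 + 1,p.W402X,p.N348K,0.95,-,-
21,HS,41 + 2,p.L218P,p.D315Y,0.35,-,-
22,HS,37 + 0,p.P533R,p.P533R,X,-,-
23,HS,37 + 0,p.P533R,p.P533R,2.43,-,-
24,S,40 + 0,p.W402X,p.R383H,1.05,-,-
25,S,40 + 0,p.Q70X,p.R383H,1.17,X,X
26,S,40 + 0,p.Q70X,p.R383H,X,X,X
27,S,X,p.A327P,p.R383H,1.70,X,X
28,S,40 + 5,c.474-2A>G,p.R383H,X,-,-
29,S,40 + 5,c.474-2A>G,p.R383H,1.61,-,-
30,S,40 + 0,c.474-2A>G,p.R383H,X,-,-
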