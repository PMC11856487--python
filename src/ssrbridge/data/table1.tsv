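genotype	platform	Dvit1	Dvit2	Dvit3	Dvit4	Dvit5	Dvit6	DVSSR3	DVSSR4
G1	polyacrylamide	128/136	259/289	175/190	159/159	131/133	211/211	237/280	248/253
G1	capillary	128.4/136.0	255.7/285.8	172.5/189.3	155.7/155.7	128.3/130.1	208.4/208.4	237.2/281.4	249.1/253.3
G1	hts	126/134	256/256/286	173/189	157/157	ND	210/210	ND	249/253
G4	polyacrylamide	128/136	259/289	175/190	159/168	133/142	199/211	237/280	253/255
G4	capillary	128.5/136.1	255.7/285.7	172.4/189.2	155.9/164.7	130.0/138.5	196.3/208.4	237.2/281.3	253.2/255.1
G4	hts	126/134	ND	ND	157/166	ND	198/210	ND	253/255
G7	polyacrylamide	134/134	259/259	175/175	156/164	132/141	205/205	237/237	250/250
G7	capillary	133.8/133.8	255.8/255.8	172.4/172.4	152.7/160.8	129.1/137.5	202.4/202.4	237.3/237.3	251.2/251.2
G7	hts	132/132	256/256	173/173	154/162	ND	ND	237/237	251/251
G19	polyacrylamide	134/136	259/259	175/175	164/164	129/129	208/208	237/258	250/253
G19	capillary	133.8/136.1	255.8/255.8	172.5/172.5	160.8/160.8	126.3/126.3	205.4/205.4	237.3/258.2	251.3/253.4
G19	hts	132/134	256/256	173/173	162/162	ND	ND	ND	251/253
G20	polyacrylamide	132/136	259/259	175/175	159/164	132/140	205/208	237/237	250/253
G20	capillary	131.8/136.1	255.9/255.9	172.6/172.6	155.7/160.8	129.0/136.5	202.4/205.4	237.2/237.2	251.2/253.3
G20	hts	130/134	256/256	173/173	157/162	ND	204/207	237/237	251/253
G30	polyacrylamide	134/134	261/261	175/175	156/164	129/132	205/205	237/258	253/253
G30	capillary	133.7/133.7	257.8/257.8	172.5/172.5	152.6/160.7	126.3/129.2	205.4/202.4	237.1/258.1	253.2/253.2
G30	hts	132/132	258/258	171/173	154/162	ND	204/204	237/259	253/253
G38	polyacrylamide	134/134	261/261	175/175	156/156	129/141	205/205	237/237	250/253
G38	capillary	133.8/133.8	257.8/257.8	172.6/172.6	152.8/152.8	126.3/137.5	202.5/202.5	237.3/237.3	251.3/253.4
G38	hts	132/132	258/258	173/173	154/154	ND	204/204	237/237	251/253
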