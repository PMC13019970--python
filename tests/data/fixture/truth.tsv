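sample_id	w_soil	w_human	w_outdoor	w_home
H1_entrance_IBZ_w-2	0	0.45	0.15	0.4
H1_entrance_IBZ_w0	0	0.45	0.15	0.4
H1_entrance_IBZ_w2	0.0999947182	0.4050023768	0.1350007923	0.3600021127
H1_entrance_IBZ_w4	0.04999471833	0.4275023767	0.1425007922	0.3800021127
H1_entrance_ABZ_w-2	0	0.45	0.15	0.4
H1_entrance_ABZ_w0	0	0.45	0.15	0.4
H1_entrance_ABZ_w2	0.06999630274	0.4185016638	0.1395005546	0.3720014789
H1_entrance_ABZ_w4	0.03499630283	0.4342516637	0.1447505546	0.3860014789
H1_LR_floor_w-2	0	0.45	0.15	0.4
H1_LR_floor_w0	0	0.45	0.15	0.4
H1_LR_floor_w2	0.02499867955	0.4387505942	0.1462501981	0.3900005282
H1_LR_floor_w4	0.01249867958	0.4443755942	0.1481251981	0.3950005282
H1_outdoor_w-2	0	0.05	0.85	0.1
H1_outdoor_w0	0	0.05	0.85	0.1
H1_outdoor_w2	0	0.05	0.85	0.1
H1_outdoor_w4	0	0.05	0.85	0.1
H2_entrance_IBZ_w-2	0	0.45	0.15	0.4
H2_entrance_IBZ_w0	0	0.45	0.15	0.4
H2_entrance_IBZ_w2	0.0499973591	0.4275011884	0.1425003961	0.3800010564
H2_entrance_IBZ_w4	0.02499735917	0.4387511884	0.1462503961	0.3900010563
H2_entrance_ABZ_w-2	0	0.45	0.15	0.4
H2_entrance_ABZ_w0	0	0.45	0.15	0.4
H2_entrance_ABZ_w2	0.03499815137	0.4342508319	0.1447502773	0.3860007395
H2_entrance_ABZ_w4	0.01749815142	0.4421258319	0.1473752773	0.3930007394
H2_LR_floor_w-2	0	0.45	0.15	0.4
H2_LR_floor_w0	0	0.45	0.15	0.4
H2_LR_floor_w2	0.01249933977	0.4443752971	0.148125099	0.3950002641
H2_LR_floor_w4	0.006249339792	0.4471877971	0.149062599	0.3975002641
H2_outdoor_w-2	0	0.05	0.85	0.1
H2_outdoor_w0	0	0.05	0.85	0.1
H2_outdoor_w2	0	0.05	0.85	0.1
H2_outdoor_w4	0	0.05	0.85	0.1
C1_entrance_IBZ_w-2	0	0.45	0.15	0.4
C1_entrance_IBZ_w0	0	0.45	0.15	0.4
C1_entrance_IBZ_w2	0	0.45	0.15	0.4
C1_entrance_IBZ_w4	0	0.45	0.15	0.4
C1_entrance_ABZ_w-2	0	0.45	0.15	0.4
C1_entrance_ABZ_w0	0	0.45	0.15	0.4
C1_entrance_ABZ_w2	0	0.45	0.15	0.4
C1_entrance_ABZ_w4	0	0.45	0.15	0.4
C1_LR_floor_w-2	0	0.45	0.15	0.4
C1_LR_floor_w0	0	0.45	0.15	0.4
C1_LR_floor_w2	0	0.45	0.15	0.4
C1_LR_floor_w4	0	0.45	0.15	0.4
C1_outdoor_w-2	0	0.05	0.85	0.1
C1_outdoor_w0	0	0.05	0.85	0.1
C1_outdoor_w2	0	0.05	0.85	0.1
C1_outdoor_w4	0	0.05	0.85	0.1
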