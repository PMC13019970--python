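sample_id	home	sample_type	location	height	week	is_control_home	kingdom
H1_entrance_IBZ_w-2	H1	settled_dust	entrance	IBZ	-2	False	bacteria
H1_entrance_IBZ_w0	H1	settled_dust	entrance	IBZ	0	False	bacteria
H1_entrance_IBZ_w2	H1	settled_dust	entrance	IBZ	2	False	bacteria
H1_entrance_IBZ_w4	H1	settled_dust	entrance	IBZ	4	False	bacteria
H1_entrance_ABZ_w-2	H1	settled_dust	entrance	ABZ	-2	False	bacteria
H1_entrance_ABZ_w0	H1	settled_dust	entrance	ABZ	0	False	bacteria
H1_entrance_ABZ_w2	H1	settled_dust	entrance	ABZ	2	False	bacteria
H1_entrance_ABZ_w4	H1	settled_dust	entrance	ABZ	4	False	bacteria
H1_LR_floor_w-2	H1	floor_dust	floor	none	-2	False	bacteria
H1_LR_floor_w0	H1	floor_dust	floor	none	0	False	bacteria
H1_LR_floor_w2	H1	floor_dust	floor	none	2	False	bacteria
H1_LR_floor_w4	H1	floor_dust	floor	none	4	False	bacteria
H1_outdoor_w-2	H1	settled_dust	outdoor	none	-2	False	bacteria
H1_outdoor_w0	H1	settled_dust	outdoor	none	0	False	bacteria
H1_outdoor_w2	H1	settled_dust	outdoor	none	2	False	bacteria
H1_outdoor_w4	H1	settled_dust	outdoor	none	4	False	bacteria
H2_entrance_IBZ_w-2	H2	settled_dust	entrance	IBZ	-2	False	bacteria
H2_entrance_IBZ_w0	H2	settled_dust	entrance	IBZ	0	False	bacteria
H2_entrance_IBZ_w2	H2	settled_dust	entrance	IBZ	2	False	bacteria
H2_entrance_IBZ_w4	H2	settled_dust	entrance	IBZ	4	False	bacteria
H2_entrance_ABZ_w-2	H2	settled_dust	entrance	ABZ	-2	False	bacteria
H2_entrance_ABZ_w0	H2	settled_dust	entrance	ABZ	0	False	bacteria
H2_entrance_ABZ_w2	H2	settled_dust	entrance	ABZ	2	False	bacteria
H2_entrance_ABZ_w4	H2	settled_dust	entrance	ABZ	4	False	bacteria
H2_LR_floor_w-2	H2	floor_dust	floor	none	-2	False	bacteria
H2_LR_floor_w0	H2	floor_dust	floor	none	0	False	bacteria
H2_LR_floor_w2	H2	floor_dust	floor	none	2	False	bacteria
H2_LR_floor_w4	H2	floor_dust	floor	none	4	False	bacteria
H2_outdoor_w-2	H2	settled_dust	outdoor	none	-2	False	bacteria
H2_outdoor_w0	H2	settled_dust	outdoor	none	0	False	bacteria
H2_outdoor_w2	H2	settled_dust	outdoor	none	2	False	bacteria
H2_outdoor_w4	H2	settled_dust	outdoor	none	4	False	bacteria
C1_entrance_IBZ_w-2	C1	settled_dust	entrance	IBZ	-2	True	bacteria
C1_entrance_IBZ_w0	C1	settled_dust	entrance	IBZ	0	True	bacteria
C1_entrance_IBZ_w2	C1	settled_dust	entrance	IBZ	2	True	bacteria
C1_entrance_IBZ_w4	C1	settled_dust	entrance	IBZ	4	True	bacteria
C1_entrance_ABZ_w-2	C1	settled_dust	entrance	ABZ	-2	True	bacteria
C1_entrance_ABZ_w0	C1	settled_dust	entrance	ABZ	0	True	bacteria
C1_entrance_ABZ_w2	C1	settled_dust	entrance	ABZ	2	True	bacteria
C1_entrance_ABZ_w4	C1	settled_dust	entrance	ABZ	4	True	bacteria
C1_LR_floor_w-2	C1	floor_dust	floor	none	-2	True	bacteria
C1_LR_floor_w0	C1	floor_dust	floor	none	0	True	bacteria
C1_LR_floor_w2	C1	floor_dust	floor	none	2	True	bacteria
C1_LR_floor_w4	C1	floor_dust	floor	none	4	True	bacteria
C1_outdoor_w-2	C1	settled_dust	outdoor	none	-2	True	bacteria
C1_outdoor_w0	C1	settled_dust	outdoor	none	0	True	bacteria
C1_outdoor_w2	C1	settled_dust	outdoor	none	2	True	bacteria
C1_outdoor_w4	C1	settled_dust	outdoor	none	4	True	bacteria
H1_soil_w0_r1	H1	source_aliquot	source	none	0	False	bacteria
H1_soil_w0_r2	H1	source_aliquot	source	none	0	False	bacteria
H2_soil_w0_r1	H2	source_aliquot	source	none	0	False	bacteria
H2_soil_w0_r2	H2	source_aliquot	source	none	0	False	bacteria
BLANK_1	none	control_blank	none	none	-2	False	bacteria
BLANK_2	none	control_blank	none	none	-2	False	bacteria
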