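chromosome	genomic_position	mature_name	position_in_mirna	editing_type
2	65308161	ssc-miR-23a	4	A-to-G
2	65308350	ssc-miR-27a	4	A-to-G
4	6952809	ssc-miR-30b-5p	5	A-to-G
4	6952808	ssc-miR-30b-5p	5	A-to-G
11	17757478	ssc-miR-15a	5	A-to-G
12	52422400	ssc-miR-497	2	A-to-G
12	52422397	ssc-miR-497	5	A-to-G
13	100083195	ssc-miR-15b	5	A-to-G
13	31655056	ssc-miR-425-5p	7	A-to-G
2	65308351	ssc-miR-27a	5	C-to-U
12	46211541	ssc-miR-423-5p	8	C-to-U
14	6520933	ssc-miR-320	6	C-to-U
1	224065570	ssc-miR-204	2	U-to-C
2	150580147	ssc-miR-145-5p	7	U-to-C
2	65308354	ssc-miR-27a	8	U-to-C
6	58332107	ssc-let-7e	6	U-to-C
12	45088852	ssc-miR-451	8	U-to-C
12	43337029	ssc-miR-193a-5p	5	U-to-C
13	189138833	ssc-miR-155-5p	2	U-to-C
15	120453426	ssc-miR-26b-5p	7	U-to-C
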