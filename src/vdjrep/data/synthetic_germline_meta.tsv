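name	segment_class	genomic_order_index	fr1_start	cdr1_start	fr2_start	cdr2_start	fr3_start	fr3_end	anchor
IGHV1-18	V	9	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV1-2	V	1	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV1-24	V	11	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV1-3	V	2	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV1-45	V	18	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV1-46	V	19	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV1-58	V	23	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV1-69	V	28	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV1-8	V	6	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV2-26	V	12	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV2-5	V	4	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV2-70	V	29	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV3-11	V	7	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV3-15	V	8	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV3-23	V	10	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV3-30	V	13	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV3-33	V	15	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV3-48	V	20	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV3-53	V	22	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV3-64	V	26	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV3-66	V	27	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV3-7	V	5	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV3-72	V	30	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV3-73	V	31	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV3-74	V	32	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV4-31	V	14	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV4-34	V	16	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV4-39	V	17	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV4-59	V	24	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV4-61	V	25	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV5-51	V	21	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV6-1	V	0	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHV7-4-1	V	3	0.0	75.0	99.0	150.0	174.0	288.0	288
IGHD1-1	D	0							
IGHD1-26	D	13							
IGHD2-15	D	7							
IGHD2-2	D	1							
IGHD2-21	D	11							
IGHD3-10	D	4							
IGHD3-22	D	12							
IGHD3-3	D	2							
IGHD3-9	D	3							
IGHD4-17	D	8							
IGHD5-12	D	5							
IGHD5-18	D	9							
IGHD6-13	D	6							
IGHD6-19	D	10							
IGHD7-27	D	14							
IGHJ1	J	0							4
IGHJ2	J	1							4
IGHJ3	J	2							6
IGHJ4	J	3							8
IGHJ5	J	4							6
IGHJ6	J	5							5
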