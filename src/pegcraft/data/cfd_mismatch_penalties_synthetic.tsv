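# Synthetic stand-in for a CFD mismatch-penalty table (same schema as
# the published resource: one penalty in [0,1] per spacer/target base
# mismatch per spacer position; positions 1-20 from the spacer 5' end,
# position 20 PAM-adjacent). Values follow a plausible structure:
# PAM-proximal mismatches are penalised harder, wobble-like pairs less.
spacer_base	target_base	position	penalty
A	C	1	0.8
A	C	2	0.7605
A	C	3	0.7211
A	C	4	0.6816
A	C	5	0.6421
A	C	6	0.6026
A	C	7	0.5632
A	C	8	0.5237
A	C	9	0.4842
A	C	10	0.4447
A	C	11	0.4053
A	C	12	0.3658
A	C	13	0.3263
A	C	14	0.2868
A	C	15	0.2474
A	C	16	0.2079
A	C	17	0.1684
A	C	18	0.1289
A	C	19	0.0895
A	C	20	0.05
A	G	1	0.85
A	G	2	0.8204
A	G	3	0.7908
A	G	4	0.7612
A	G	5	0.7316
A	G	6	0.702
A	G	7	0.6724
A	G	8	0.6428
A	G	9	0.6132
A	G	10	0.5836
A	G	11	0.5539
A	G	12	0.5243
A	G	13	0.4947
A	G	14	0.4651
A	G	15	0.4355
A	G	16	0.4059
A	G	17	0.3763
A	G	18	0.3467
A	G	19	0.3171
A	G	20	0.2875
A	T	1	0.8
A	T	2	0.7605
A	T	3	0.7211
A	T	4	0.6816
A	T	5	0.6421
A	T	6	0.6026
A	T	7	0.5632
A	T	8	0.5237
A	T	9	0.4842
A	T	10	0.4447
A	T	11	0.4053
A	T	12	0.3658
A	T	13	0.3263
A	T	14	0.2868
A	T	15	0.2474
A	T	16	0.2079
A	T	17	0.1684
A	T	18	0.1289
A	T	19	0.0895
A	T	20	0.05
C	A	1	0.8
C	A	2	0.7605
C	A	3	0.7211
C	A	4	0.6816
C	A	5	0.6421
C	A	6	0.6026
C	A	7	0.5632
C	A	8	0.5237
C	A	9	0.4842
C	A	10	0.4447
C	A	11	0.4053
C	A	12	0.3658
C	A	13	0.3263
C	A	14	0.2868
C	A	15	0.2474
C	A	16	0.2079
C	A	17	0.1684
C	A	18	0.1289
C	A	19	0.0895
C	A	20	0.05
C	G	1	0.8
C	G	2	0.7605
C	G	3	0.7211
C	G	4	0.6816
C	G	5	0.6421
C	G	6	0.6026
C	G	7	0.5632
C	G	8	0.5237
C	G	9	0.4842
C	G	10	0.4447
C	G	11	0.4053
C	G	12	0.3658
C	G	13	0.3263
C	G	14	0.2868
C	G	15	0.2474
C	G	16	0.2079
C	G	17	0.1684
C	G	18	0.1289
C	G	19	0.0895
C	G	20	0.05
C	T	1	0.85
C	T	2	0.8204
C	T	3	0.7908
C	T	4	0.7612
C	T	5	0.7316
C	T	6	0.702
C	T	7	0.6724
C	T	8	0.6428
C	T	9	0.6132
C	T	10	0.5836
C	T	11	0.5539
C	T	12	0.5243
C	T	13	0.4947
C	T	14	0.4651
C	T	15	0.4355
C	T	16	0.4059
C	T	17	0.3763
C	T	18	0.3467
C	T	19	0.3171
C	T	20	0.2875
G	A	1	0.85
G	A	2	0.8204
G	A	3	0.7908
G	A	4	0.7612
G	A	5	0.7316
G	A	6	0.702
G	A	7	0.6724
G	A	8	0.6428
G	A	9	0.6132
G	A	10	0.5836
G	A	11	0.5539
G	A	12	0.5243
G	A	13	0.4947
G	A	14	0.4651
G	A	15	0.4355
G	A	16	0.4059
G	A	17	0.3763
G	A	18	0.3467
G	A	19	0.3171
G	A	20	0.2875
G	C	1	0.8
G	C	2	0.7605
G	C	3	0.7211
G	C	4	0.6816
G	C	5	0.6421
G	C	6	0.6026
G	C	7	0.5632
G	C	8	0.5237
G	C	9	0.4842
G	C	10	0.4447
G	C	11	0.4053
G	C	12	0.3658
G	C	13	0.3263
G	C	14	0.2868
G	C	15	0.2474
G	C	16	0.2079
G	C	17	0.1684
G	C	18	0.1289
G	C	19	0.0895
G	C	20	0.05
G	T	1	0.91
G	T	2	0.8922
G	T	3	0.8745
G	T	4	0.8567
G	T	5	0.8389
G	T	6	0.8212
G	T	7	0.8034
G	T	8	0.7857
G	T	9	0.7679
G	T	10	0.7501
G	T	11	0.7324
G	T	12	0.7146
G	T	13	0.6968
G	T	14	0.6791
G	T	15	0.6613
G	T	16	0.6436
G	T	17	0.6258
G	T	18	0.608
G	T	19	0.5903
G	T	20	0.5725
T	A	1	0.8
T	A	2	0.7605
T	A	3	0.7211
T	A	4	0.6816
T	A	5	0.6421
T	A	6	0.6026
T	A	7	0.5632
T	A	8	0.5237
T	A	9	0.4842
T	A	10	0.4447
T	A	11	0.4053
T	A	12	0.3658
T	A	13	0.3263
T	A	14	0.2868
T	A	15	0.2474
T	A	16	0.2079
T	A	17	0.1684
T	A	18	0.1289
T	A	19	0.0895
T	A	20	0.05
T	C	1	0.85
T	C	2	0.8204
T	C	3	0.7908
T	C	4	0.7612
T	C	5	0.7316
T	C	6	0.702
T	C	7	0.6724
T	C	8	0.6428
T	C	9	0.6132
T	C	10	0.5836
T	C	11	0.5539
T	C	12	0.5243
T	C	13	0.4947
T	C	14	0.4651
T	C	15	0.4355
T	C	16	0.4059
T	C	17	0.3763
T	C	18	0.3467
T	C	19	0.3171
T	C	20	0.2875
T	G	1	0.9
T	G	2	0.8803
T	G	3	0.8605
T	G	4	0.8408
T	G	5	0.8211
T	G	6	0.8013
T	G	7	0.7816
T	G	8	0.7618
T	G	9	0.7421
T	G	10	0.7224
T	G	11	0.7026
T	G	12	0.6829
T	G	13	0.6632
T	G	14	0.6434
T	G	15	0.6237
T	G	16	0.6039
T	G	17	0.5842
T	G	18	0.5645
T	G	19	0.5447
T	G	20	0.525
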