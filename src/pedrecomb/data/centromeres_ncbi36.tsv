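chrom	centromere_bp	length_bp
1	121200000	247249719
2	91000000	242951149
3	90400000	199501827
4	49400000	191273063
5	46400000	180857866
6	58900000	170899992
7	58100000	158821424
8	43900000	146274826
9	46700000	140273252
10	39300000	135374737
11	51400000	134452384
12	34700000	132349534
13	16000000	114142980
14	15600000	106368585
15	15900000	100338915
16	36200000	88827254
17	22100000	78774742
18	16100000	76117153
19	28500000	63811651
20	27100000	62435964
21	12300000	46944323
22	11800000	49691432
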