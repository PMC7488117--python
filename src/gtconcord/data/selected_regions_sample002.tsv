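Chromosome	Start	End	INDELs	SNVs	Total
1	109711850	109712150	0	3	3
1	109759300	109759400	1	0	1
2	85663600	85663700	1	0	1
2	233671750	233671850	1	0	1
6	160246180	160246690	0	3	3
10	101010500	101010600	1	0	1
13	49792500	49792600	1	0	1
22	37973800	37974170	1	0	1
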