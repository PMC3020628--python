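locality	latitude_s	n_coi	n_rbcl	region
Pichicuy	32.3455	10	8	central
Montemar	32.9576	10	10	central
Cartagena	33.5509	6	0	central
Matanzas	33.7659	5	0	central
Pichilemu	34.3938	6	0	central
Duao	34.8868	7	0	central
Constitucion	35.3281	6	9	central
Dichato	36.4950	6	0	central
Tumbes	36.6154	8	9	central
Lebu	37.5950	5	0	central
Tirua	38.3452	4	0	central
Queule	39.3880	5	0	central
Punta Loncoyen	39.8245	9	9	central
Bahia Mansa	40.5928	5	0	central
Pumillahue	41.9458	8	0	central
Cucao	42.6689	10	9	central
Isla Guafo	43.5548	5	0	central
Puerto Barrientos	43.9123	6	0	central
Isla Betecoi	43.9855	9	0	central
49S	49.1569	7	10	patagonia
50S	50.1491	10	10	patagonia
51S	51.7788	6	0	patagonia
53S	53.6553	7	0	patagonia
Cape Horn	55.9921	4	4	patagonia
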