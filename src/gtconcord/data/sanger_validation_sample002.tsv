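rsID	Chromosome	Position	BeadChip genotype	WGS genotype	Sanger genotype	Note
rs12731384	1	109711898	TG	GG	TT	d
rs1633365	1	109711919	TC	TT	TC	c
rs58877308	1	109712113	CG	GG	GG	a
rs138687644	1	109759369	GG	GG	G-
rs202018423	1	109759339	CC	CC	CC	b
rs757293027	1	109759384	CC	CC	C-
rs760279355	1	109759346	CC	CC	CC	b
rs767809812	1	109759359	DD	II	I-
rs79394341	1	109759361	GG	GG	G-
rs786205634	2	85663647	DI	II	II	a
rs3832043	2	233671807	II	DI	DD	d
rs144484152	6	160246683	GG	AA	AA	a
rs149262397	6	160246574	CC	CC	CC	b
rs316022	6	160246568	GG	AA	AA	a
rs529525717	6	160246473	GG	GG	GG	b
rs537568133	6	160246590	TT	CC	CC	a
rs549969754	6	160246607	CC	CC	CC	b
rs555024471	6	160246297	GG	GG	G-
rs563560445	6	160246467	CC	CC	CC	b
rs563829592	6	160246443	GG	GG	G-
rs577352795	6	160246460	TT	TT	T-
rs757852385	6	160246688	AA	AA	AA	b
rs759566284	6	160246458	GG	GG	G-
rs200896335	10	101010536	DD	II	NA
rs753420953	13	49792587	DD	DI	NA
rs397515367	22	37973817	DD	II	II	a
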