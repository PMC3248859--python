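repeat_id	links	five_prime_contig	three_prime_contig
Repeat 1	3990	Contig00011	Contig00012
	3226	Contig00059	Contig00050
	206	Contig00012	Contig00050
	210	Contig00011	Contig00059
Repeat 2	810	Contig00001	Contig00026
	615	Contig00004	Contig00032
	333	Contig00001	Contig00004
	186	Contig00026	Contig00032
Repeat 3	53	Contig00026	Contig00281
	51	Contig00395	Contig200056
	31	Contig00026	Contig00395
	14	Contig00281	Contig200056
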