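element	five_prime_nick	tsd	three_prime_nick
Sadhu1-1	tacaaaagt	aaatgactagtagga	taataaaca
Sadhu1-2	acttgacat	agctatgaaaatcgt	tggaccatc
Sadhu3-2	tttatgaag	aatcttcgtt	cagtcctgc
Sadhu4-2	acaacattt	aaagatatctcgtttg	tggagaacg
Sadhu5-1	ctgcaatat	agtactactact	aatgttatc
Sadhu5-1d1	ttaagaaag	aaatgtgtctcaacg	cgaccaacg
Sadhu6-1	gaagagacc	aaaacctagtctggag	tacaaagta
Sadhu6-1d2	ttataaaag	aaaactaatcttaa	gaaaaatac
Sadhu7-1	atggaagat	aaagaatctggcttt	ttgtaaaac
Sadhu7-2	ctatggaag	aagaaggtaa	ccaactact
Sadhu7L1	agggagttt	ttaagag	ttttattat
Sadhu7L2	tcatataat	aattacctagca	cgaaatcta
Sadhu8-1	gaacataac	aaaagatccaa	acgtatggt
Sadhu9L3	caatcaacc	ccgtatt	gtagatttt
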