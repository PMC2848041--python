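name	locus_id	genome_position
Sadhu1-1	At2g10410	Chr2: 4014110-4013202
Sadhu1-2	At1g30835	Chr1: 10967854-10966931
Sadhu1-3	At5g28626	Chr5: 10632245-10632826; 10633568-10633948
Sadhu1L1	At1g66795	Chr1: 24926769-24927016
Sadhu2-1	At1g35112	Chr1: 12841125-12840206
Sadhu2-1d1	At2g18535	Chr2: 8048795-8048610
Sadhu3-1	At3g44042	Chr3: 15825096-15824141
Sadhu3-2	At3g42658	Chr3: 14761424-14760388
Sadhu3-1d1	At2g21905	Chr2: 9345876-9346247
Sadhu3-1d2	At5g03205	Chr5: 762065-761915
Sadhu3L1	At4g04925	Chr4: 2506188-2506806
Sadhu4-1	At5g28913	Chr5: 10934749-10933814
Sadhu4-2	At1g03420	Chr1: 846815-847698
Sadhu4-2d1	At2g05027	Chr2: 1781076-1781386
Sadhu5-1	At4g01525	Chr4: 660768-661723
Sadhu5-1d1	At1g18195	Chr1: 6262595-6263382
Sadhu5-1d2	At4g00953	Chr4: 410383-411018
Sadhu5-2	At5g27927	Chr5: 9957820-9956864
Sadhu6-1	At3g02515	Chr3: 525338-526263
Sadhu6-1d1	At5g42095	Chr5: 16845951-16846349
Sadhu6-1d2	At5g44565	Chr5: 17981087-17980529
Sadhu6-1d3	At5g42237	Chr5: 16987448-16988447
Sadhu6L1	At2g10935	Chr2: 4312891-4312205
Sadhu7-1	At3g13438	Chr3: 4377991-4377083
Sadhu7-2	At3g31442	Chr3: 12807354-12806392
Sadhu7L1	At1g36745	Chr1: 13912120-13913031
Sadhu7L2	At3g61625	Chr3: 22815058-22814684
Sadhu7L3	At5g52140	Chr5: 21206508-21206698
Sadhu8-1	At1g50735	Chr1: 18811080-18810175
Sadhu8L1	At5g38915	Chr5: 15597647-15597844
Sadhu8L2	At2g24745	Chr2: 10540693-10541337
Sadhu8L3	At1g52615	Chr1: 19607182-19606826
Sadhu9-1	At1g44935	Chr1: 16904928-16905344
Sadhu9L1	At1g32455	Chr1: 11733481-11733785
Sadhu9L2	At1g69365	Chr1: 26083199-26083479
Sadhu10-1	At3g58865	Chr3: 21776975-21777729
Sadhu10L1	At5g46395	Chr5: 18836667-18837050
Sadhu10L2	At5g42945	Chr5: 17240081-17240294
Sadhu10L3	At1g35255	Chr1: 12935906-12936263
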