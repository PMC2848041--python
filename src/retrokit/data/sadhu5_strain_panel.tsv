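strain	stock	Sadhu5-1_int	Sadhu5-1_5	Sadhu5-1_3	Sadhu5-1d1_int	Sadhu5-1d1_5	Sadhu5-1d1_3	Sadhu5-1d2_int	Sadhu5-1d2_5	Sadhu5-1d2_3	Sadhu5-2_int	Sadhu5-2_5	Sadhu5-2_3
Br-0	CS22628	ES			ES			X	X	X	X	X	X
Bur-0	CS22656				X	X	X	X	X	X	X	X	X
C24	CS22620				ES			X	X	X	X	X	X
Col	Lehle WT-2	X	X	X	X	X	X	X	X	X	X	X	X
Ct-1	CS22639	ES			ES			X	X	X	X	X	X
Cvi	Lehle WT-18	X	X*	X*	X	X*	X*	X	X	X	X	X	X
Cvi-0	CS22614				X	X	X	X	X	X	X	X	X
Fei-0	CS22645				ES			X	X	X	X	X	X
Hi-0	CS6736	X		X	ES			X	X	X	X	X
Kn-0	CS6762	X	Short	X	ES			X	X	X	X	X	X
Kondara	CS22651	X	Long	X							X	X	X
Kz-1	CS22606	X	X*	X*				X*	X	X	X	X	X
Ler	Lehle WT-4	X			ES			X	X	X	X	X*
N13	CS22491	X	X*	X	ES			X	X	X	X	X	X
Po-0	CS6839	X	X*	X*	ES			X	X	X	X	X	X
Pro-0	CS22649	X	X*	X				X*	X	X	X	X	X
Pu2-7	CS22592	X	X*	X	ES			X	X	X	X	X	X
Ra-0	CS22632	X	X	X				X	X	X	X	X	X
Tamm-27	CS22605	X	X	X	ES						X	X	X
Ts-1	CS22647				ES			X	X	X	X	X	X
Tsu-1	CS22641	X	X	X	ES			X	X	X	X	X	X
Van-0	CS22627	X	X	X				X	X	X	X	X	X
Wei-0	CS22622	X	X	X	ES			X*	X	X	X	X	X
Ws-2	CS22659	X	Long	X				X	X	X	X	X	X
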