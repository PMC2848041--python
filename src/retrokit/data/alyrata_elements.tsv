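name	scaffold_coordinates	orientation	length_bp	tsd_bp	full_length	pct_identity_nearest
AlSadhu1-1	7:7309496-7310418	-	948	18	Yes	86
AlSadhu1-2	8:11697563-11698467	+	922	12	Yes	86
AlSadhu1-3	6:22517373-22518173	+	957	14	Yes	84
AlSadhu1-4	3:1662010-1662618	-	1009	14	Yes	81
AlSadhu1-5	1:24954753-24955365	+	924	ND	Yes	84
AlSadhu1-6	4:841417-842023	+	965	16	Yes	82
AlSadhu1-6	3:13675822-13676434	+	927	16	Yes	84
AlSadhu1d	2:14298861-14299465	+	827	ND	No	81
AlSadhu3-1	7:12620425-12621361	+	928	18	Yes	86
AlSadhu5-1	7:17697122-17698008	+	879	11	Yes	85
AlSadhu5d	6:5062639-5062768	-	791	ND	No	72
AlSadhu5d2	6:25041036-25041746	+	804	ND	No	73
AlSadhu5d3	5:4156620-4157046	-	395	ND	No	71
AlSadhu6-1	3:21898960-21899646	-	899	14	Yes	77
AlSadhu6-2	2:14183205-14186662	+	887*	15	Yes	77
AlSadhu6-3	8:5795744-5796493	+	927	ND	Yes	78
AlSadhu7-1	7:4360460-4360769	-	901	16	Yes	79
AlSadhu8-1	1:13276396-13277158	-	920	13	Yes	77
AlSadhu8-2	3:807549-808169	+	865	ND	Yes	79
AlSadhu8-3	2:25942-26642	+	908	8	Yes	77
AlSadhu8-4	8:14602238-14602861	+	875	15	Yes	75
AlSadhu8-5	7:17882685-17884241	+	930**	ND	Yes	78
AlSadhu8-6	6:17227119-17227908	-	910	ND	Yes	77
AlSadhu10-1	3:4473616-4474232	+	918	17	Yes	80
AlSadhu10-2	2:9675105-9675721	+	895	ND	Yes	80
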