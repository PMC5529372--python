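candidate_id	chromosome	start	end	strand	arm	mature_sequence	energy_kcal_mol
miR-N1	2L	37758152	37758241	-	3p	CUCAUCAAUUGGUUGUGGCUAUG	-26.30
miR-N2	3L	17216211	17216296	+	5p	AUUAGAAUGUGGAAUCUGUUUU	-22.30
miR-N3	Unknown	30034502	30034587	-	3p	UGACUUGUCUGCCUGAGCAAGGGG	-32.70
miR-N4	2R	36376058	36376154	-	3p	AAGACGCUGGUUCUCUUCACACA	-27.50
miR-N5	X	1722538	1722623	-	3p	UUGGGCGCUAUCUACAAUGUAG	-26.66
miR-N6	Unknown	30034504	30034585	-	3p	UAUGACUUGUCUGCCUGAGCAAGG	-32.70
miR-N7	Unknown	9226296	9226379	-	3p	GUGGAACCGCGUAGGCUGCCU	-22.90
miR-N8	X	23502516	23502590	+	3p	UGACGGGUUUGGUCUCUCCA	-57.50
miR-N9	2L	48562288	48562365	+	5p	UAGUCGUUUUCUGCUUUGCGGUU	-20.30
miR-N10	3R	44916363	44916443	-	3p	UGUUCGAUCGUUACUGUCAUAU	-24.00
miR-N11	2R	18852629	18852719	-	5p	CGUGGUACUCUUGUGGUAAGG	-39.20
miR-N12	2R	7197866	7197955	-	3p	UGCAUUCAGUGGGGCGGUCGUG	-42.89
miR-N13	3L	7171866	7171950	-	5p	AGCUGUUCUGACUUGAUGUACU	-28.31
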