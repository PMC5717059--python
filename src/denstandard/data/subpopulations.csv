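landscape,adults_2012,adults_2000,breeding_females_2012,breeding_females_2000,tigers_minus_1se,tigers_plus_1se,priority
Ulu Masen,45,51,16,17,24,66,1
Gunung Leuser,140,154,48,53,74,206,1
Sibolga & Bt Toru,52,54,18,18,27,76,1
Bt Gadis/Rimbo-Panti,61,67,21,23,32,89,1
Rimbang Baling & Bt Hari,53,71,18,25,28,77,1
Kerinci Seblat,122,145,42,50,65,180,1
Bk Barisan Selatan,41,46,14,16,22,61,1
Bk Tiga Puluh,22,36,7,12,12,32,0
Senepis-Buluhala,14,23,5,8,7,20,0
Kuala Kampar & Keremutan,26,42,9,15,14,38,0
Tesso Nilo,6,13,2,5,3,9,0
Bk Dua Belas,3,5,1,2,2,4,0
Berbak,16,17,5,6,8,23,0
Harapan,8,9,3,3,4,12,0
Way Kambas,10,10,3,3,5,15,0
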