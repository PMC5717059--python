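landscape,montane_primary_km2,lowland_hill_primary_km2,peat_primary_km2,lowland_hill_degraded_km2,peat_degraded_km2,total_2012_thousand_km2,deforestation_12yr_pct
Ulu Masen,4271,599,0,1884,0,6.8,8.8
Gunung Leuser,14332,1890,1,4969,119,21.3,7.6
Sibolga & Bt Toru,5521,0,0,2711,23,8.3,4.5
Bt Gadis/Rimbo-Panti,4563,579,0,3693,130,9.0,7.8
Rimbang Baling & Bt Hari,1659,1710,0,3143,0,6.5,24.5
Kerinci Seblat,10330,3010,0,4017,6,17.4,12.8
Bk Barisan Selatan,3188,1128,0,1397,0,5.7,9.7
Bk Tiga Puluh,0,0,0,2842,0,2.8,39.1
Senepis-Buluhala,0,0,732,87,2309,3.1,40.9
Kuala Kampar & Keremutan,0,0,659,108,5500,6.3,38.8
Tesso Nilo,0,0,0,740,125,0.9,55.3
Bk Dua Belas,0,0,0,391,0,0.4,36.9
Berbak,0,0,0,687,2721,3.4,11.7
Harapan,0,0,0,1108,0,1.1,7.2
Way Kambas,0,0,0,1312,9,1.3,5.1
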