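no,compound,descriptor,identification,ri_gc,ri_snif,nif_A0,nif_A52,nif_P0,nif_P52,is_A0,is_A52,is_P0,is_P52,oi_A0,oi_A52,oi_P0,oi_P52,rpa_A0,rpa_sd_A0,rpa_A52,rpa_sd_A52,rpa_P0,rpa_sd_P0,rpa_P52,rpa_sd_P52
1,2-Butanone,"Fruity, solvent","m,r,a,s",908,919,89,100,0,56,55,42,0,23,70,65,0,36,0.12,0.02,0.11,0.02,0.14,0.04,0.13,0.05
2,2-Methyl-2-propanol,"Chemical, solvent","m,r,a",916,917,11,0,56,44,8,0,24,20,9,0,36,30,0.16,0.03,0.19,0.07,0.16,0.06,0.18,0.05
3,Diacetyl,Caramel,"m,r,a,s",975,981,78,78,78,78,48,50,48,53,61,63,61,64,0.01,0.02,0.004,0.002,0.01,0.01,0.002,0.002
4,Unidentified (roasted),Roasted,,1053,1051,44,67,56,33,25,23,15,10,33,39,29,18,0.05,0.01,0.03,0.01,0.04,0.02,0.08,0.06
5,Ethyl butyrate,"Fruity, pineapple","r,a,s",,1068,78,44,56,78,46,19,32,38,60,29,42,54,,,,,,,,
6,"2,3-Pentanedione",Caramel,"r,a",,1075,56,33,44,33,29,9,30,13,40,18,37,21,,,,,,,,
7,Hexanal,"Grass, green, flower","m,r,a,s",1096,1088,100,89,89,89,61,46,55,52,78,64,70,68,1.77,0.32,0.29,0.08,1.14,0.25,0.25,0.16
8,2-Methyl-1-propanol,"Plastic, rubber","m,r,a,s",1110,1110,67,67,56,67,42,37,35,40,53,49,44,51,0.16,0.03,0.07,0.01,0.18,0.04,0.07,0.01
9,2-Butylfuran,"Plant, grass","m,r,a",1147,1147,0,33,44,22,0,16,21,10,0,23,30,15,0.004,0.001,0.004,0.004,0.01,0.00,0.02,0.01
10,Unidentified (potato),"Potato, plastic, beany",,1172,1176,56,0,56,44,22,0,18,15,35,0,32,26,0.02,0.00,0.01,0.00,0.02,0.00,0.03,0.01
11,Pyridine,"Vegetable, plants, sharp, rubber","m,r,a,s",1199,1205,56,67,56,56,26,30,28,21,38,45,39,34,0.41,0.07,0.75,0.11,0.95,0.27,0.62,0.21
12,2-Hexenal,"Flower, perfume, paint","m,r,a",1217,1217,56,11,33,33,35,4,22,17,44,7,27,24,0.06,0.01,0.03,0.01,0.07,0.01,0.04,0.01
13,3-Methyl-1-butanol,"Off-flavour, cheesy, socks","m,r,a,s",1227,1225,100,100,44,100,64,63,34,56,80,79,39,75,0.93,0.06,0.25,0.05,0.76,0.10,0.79,0.09
14,2-Pentyl-furan,"Minty, candy, fruity","m,r,a,s",1245,1247,11,44,56,22,8,18,22,13,9,28,35,17,0.08,0.02,0.08,0.01,0.40,0.12,0.14,0.04
15,Unidentified (beany),"Plant, beany, spicy",,1254,1259,78,33,56,56,46,23,32,32,60,28,42,42,0.004,0.004,0.01,0.01,0.01,0.01,0.002,0.001
16,Octanal,"Citrus, orange","m,r,a,s",1313,1313,89,56,89,78,57,38,55,44,71,46,70,58,0.05,0.01,0.03,0.01,0.09,0.02,0.04,0.02
17,1-Octen-3-one,"Mushroom, vegetable","m,r,a,s",1324,1326,78,89,78,89,53,43,48,68,64,62,61,78,0.004,0.001,0.002,0.001,0.004,0.002,0.005,0.001
18,(E)-2-Heptenal,"Broth, cheesy","m,r,a,s",1349,1354,67,22,33,22,45,11,21,7,55,16,26,12,0.05,0.02,0.02,0.00,0.03,0.01,0.03,0.01
19,2-Acetyl-1-pyrroline,"Popcorn, cooked rice","m,r,a",1362,1368,89,56,89,67,71,40,65,42,79,47,76,53,0.02,0.00,0.02,0.00,0.03,0.00,0.02,0.00
20,Unidentified (popcorn),"Popcorn, plant, vegetable",,,1384,33,44,44,22,19,19,23,9,25,29,32,14,,,,,,,,
21,Unidentified (off),"Plant, chemical, beany, off",,1395,1401,89,78,22,78,39,45,15,39,59,59,18,55,0.003,0.005,0.001,0.001,0.001,0.001,0.003,0.002
22,Nonanal,"Grassy, green, fruity, pungent","m,r,a,s",1417,1415,100,100,100,89,64,65,62,46,80,80,79,64,0.08,0.03,0.06,0.02,0.13,0.04,0.06,0.03
23,Unidentified (minty),"Minty, mushroom, grassy, fruity, flowery",,1437,1437,56,44,67,44,34,19,41,15,44,29,52,26,0.01,0.00,0.002,0.002,0.04,0.01,0.003,0.003
24,Unidentified (rubber),"Rubber, mint, methoxypyrazine",,1445,1448,22,67,11,56,16,43,10,33,19,53,11,43,0.001,0.001,0.002,0.001,0.002,0.002,0.003,0.002
25,Acetic acid,"Beany, green, nutty, earthy","m,r,a,s",1459,1460,89,78,100,89,75,62,74,70,82,70,86,79,0.01,0.00,0.003,0.005,0.01,0.01,0.005,0.002
26,Methional,"Potato, beany, pea","m,r,a",1478,1480,67,89,33,67,38,51,20,37,50,67,26,50,0.01,0.00,0.01,0.00,0.01,0.00,0.01,0.00
27,Furfural,"Fries, potato, cheesy","m,r,a",1483,1487,67,0,22,44,45,0,14,32,55,0,18,38,0.18,0.03,0.18,0.03,0.23,0.07,0.26,0.15
28,Decanal,"Plants, flower, vegetables","m,r,a",1526,1528,67,67,33,22,44,38,21,11,54,50,26,15,0.03,0.01,0.03,0.01,0.04,0.02,0.03,0.02
29,Pyrrole,"Plants, nutty, pyrazine, rubbery, soap","m,r,a,s",1532,1537,44,22,44,56,18,11,15,28,28,15,26,39,0.02,0.02,0.01,0.00,0.01,0.00,0.01,0.00
30,Benzaldehyde,"Flower, plant, pea","m,r,a,s",1561,1559,67,67,89,100,45,46,55,60,55,55,70,77,0.30,0.02,0.12,0.02,0.13,0.05,0.34,0.03
31,(E)-2-Nonenal,"Leather, lipstick, perfume","m,r,a,s",1562,1570,67,33,22,44,42,22,15,29,53,27,19,36,0.04,0.03,0.03,0.03,0.04,0.03,0.09,0.09
32,"(E)-2,(Z)-6-Nonadienal",Pickled cucumber,"r,a",,1623,78,67,33,0,36,28,17,0,53,43,24,0,,,,,,,,
33,Unidentified (mushroom),"Mushroom, tofu, mould, herbs",,,1631,0,0,56,56,0,0,32,31,0,0,42,41,,,,,,,,
34,Benzonitrile,"Off, rubber","m,r,a,s",1649,1658,78,0,22,0,54,0,9,0,65,0,14,0,0.01,0.00,0.002,0.003,0.01,0.00,0.01,0.00
35,Butyrolactone,"Flower, sweet, off-flavour","r,a,s",,1665,44,44,67,56,19,26,42,33,29,34,53,43,,,,,,,,
36,2-Acetylthiazole,"Popcorn, cooked rice","m,r,a,s",1689,1688,78,89,89,89,61,68,72,62,69,78,80,74,0.06,0.04,0.06,0.04,0.10,0.06,0.11,0.08
37,Ethyl benzoate,"Beany, vegetables","m,r,a,s",1710,1707,67,33,56,33,45,17,29,10,55,24,40,18,0.02,0.01,0.02,0.01,0.02,0.02,0.03,0.01
38,Unidentified (grain),"Flower, plant, grain",,,1716,0,67,33,0,0,35,15,0,0,48,22,0,,,,,,,,
39,Unidentified (roast-bean),"Beans, oats, fish feed, roasted",,,1719,0,0,44,56,0,0,29,27,0,0,36,39,,,,,,,,
40,Damascenone,"Sweet, candy fruit","r,a,s",,1881,78,33,22,78,45,16,13,40,59,23,17,56,,,,,,,,
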