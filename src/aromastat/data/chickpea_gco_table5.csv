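rank,compound,descriptor,oi_A0,oi_A52,oi_P0,oi_P52
1,Acetic acid,"Beany, green, nutty, earthy",82,70,86,79
2,Nonanal,"Grassy, green, fruity, pungent",80,80,79,64
3,2-Acetylthiazole,"Popcorn, cooked rice",69,78,80,74
4,Hexanal,"Grass, green, flower",78,64,70,68
5,3-Methyl-1-butanol,"Cheesy, socks, off-flavour",80,79,39,75
6,1-Octen-3-one,"Mushroom, vegetable",64,62,61,78
7,Benzaldehyde,"Flower, plant, pea",55,55,70,77
8,2-Acetyl-1-pyrroline,"Popcorn, cooked rice",79,47,76,53
9,Octanal,"Citrus, orange",71,46,70,58
10,Methional,"Potato, beany, pea",50,67,26,50
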