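matrix,compartment_size,compartment_size_se,analyte,amount_nmol,se_nmol
liver,831,21,choline,194,13
liver,831,21,phosphocholine,98,8
liver,831,21,CDP-choline,1.0,0.2
liver,831,21,GPC,109,8
liver,831,21,betaine,1631,125
liver,831,21,DMG,39,2
liver,831,21,TMAO,1.0,0.3
liver,831,21,methionine,25,3
liver,831,21,PC,19900,1000
liver,831,21,lysoPC,190,10
liver,831,21,SPH,2710,100
plasma,2151,26,choline,75,7
plasma,2151,26,phosphocholine,3.8,0.6
plasma,2151,26,CDP-choline,0.4,0.1
plasma,2151,26,GPC,9,1
plasma,2151,26,betaine,242,22
plasma,2151,26,DMG,16,1
plasma,2151,26,TMAO,3.0,0.8
plasma,2151,26,methionine,4.4,0.3
plasma,2151,26,PC,4700,200
plasma,2151,26,lysoPC,440,30
plasma,2151,26,SPH,390,20
lung,282,4,choline,92,12
lung,282,4,phosphocholine,29,2
lung,282,4,CDP-choline,0.2,0.03
lung,282,4,GPC,34,2
lung,282,4,betaine,29,2
lung,282,4,DMG,2.6,0.2
lung,282,4,TMAO,1.6,0.4
lung,282,4,methionine,3.8,0.5
lung,282,4,PC,5600,300
lung,282,4,lysoPC,52,4
lung,282,4,SPH,1000,100
LLF,,,PC,500,40
LLF,,,lysoPC,2,1
LLF,,,SPH,10,3
cerebrum,881,37,choline,230,17
cerebrum,881,37,phosphocholine,375,31
cerebrum,881,37,CDP-choline,16,2
cerebrum,881,37,GPC,55,13
cerebrum,881,37,betaine,21,2
cerebrum,881,37,DMG,7.7,0.6
cerebrum,881,37,TMAO,0.31,0.07
cerebrum,881,37,methionine,24.6,4.1
cerebrum,881,37,PC,19000,1600
cerebrum,881,37,lysoPC,63,7
cerebrum,881,37,SPH,870,90
cerebellum,268,14,choline,193,29
cerebellum,268,14,phosphocholine,329,36
cerebellum,268,14,CDP-choline,13,1
cerebellum,268,14,GPC,36,7
cerebellum,268,14,betaine,15,2
cerebellum,268,14,DMG,6.5,0.9
cerebellum,268,14,TMAO,0.22,0.03
cerebellum,268,14,methionine,19.2,4.9
cerebellum,268,14,PC,5400,600
cerebellum,268,14,lysoPC,19,3
cerebellum,268,14,SPH,350,30
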