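name,formula,nominal_mass,monoisotopic_mass,n_hydroxyl,n_methoxy,n_keto,n_epoxide,compound_class,producers,diagnostic_fragments,fine_structure_low,fine_structure_high,ref_lambda_max,isomer_water_loss,observed_mass,notes
lutein,C40H56O2,568,568.428,2,0,0,0,hydroxy,plant,551:high-intensity water loss|430:literature diagnostic|494:reported alongside intense water loss|495:literature diagnostic,40,70,422;445;474,high,,dihydroxy xanthophyll; allylic 3'-OH gives the intense [M-H2O] fragment
zeaxanthin,C40H56O2,568,568.428,2,0,0,0,hydroxy,bacteria;cyanobacteria;plant,,10,35,428;450;478,low,,dihydroxy xanthophyll; classic Flavobacterium pigment
caloxanthin,C40H56O3,584,584.423,3,0,0,0,hydroxy,bacteria;cyanobacteria,,18,38,428;450;478,,,trihydroxy xanthophyll (hydroxy-zeaxanthin); Erythrobacter and cyanobacteria
capsanthin,C40H56O3,584,584.423,2,0,1,0,keto;hydroxy,plant,,0,12,450;475;505,,,keto xanthophyll of Capsicum; not a microbial product
"lutein-5,6-epoxide",C40H56O3,584,584.423,2,0,0,1,epoxy;hydroxy,plant,,75,95,417;441;470,,,epoxy xanthophyll; plant pigment
15-apo-carotenal,C20H28O,284,284.214,0,0,1,0,apo,bacteria;cyanobacteria;plant;fungi,,,,410,,283.6,apocarotenoid cleavage product; neutral mass 283.6 reported from trap data
"3,4-dihydrospirilloxanthin",C42H62O2,598,598.475,0,2,0,0,methoxy,bacteria,,55,80,443;470;500,,,acyclic dimethoxy carotenoid of Rhodospirillum
hydroxyechinenone,C40H54O2,566,566.412,1,0,1,0,keto;hydroxy,bacteria;cyanobacteria,,0,9,458,,,keto carotenoid; conjugated carbonyl smooths fine structure
astaxanthin,C40H52O4,596,596.386,2,0,2,0,keto;hydroxy,bacteria;plant;fungi,,0,12,478,,,diketo dihydroxy xanthophyll; commercial standard
canthaxanthin,C40H52O2,564,564.397,0,0,2,0,keto,bacteria;fungi,,0,10,478,,,diketo carotenoid; commercial standard
beta-carotene,C40H56,536,536.438,0,0,0,0,carotene,bacteria;cyanobacteria;plant;fungi,,15,35,425;450;478,,,hydrocarbon carotene
lycopene,C40H56,536,536.438,0,0,0,0,carotene,bacteria;plant;fungi,,55,80,444;470;502,,,acyclic hydrocarbon carotene
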