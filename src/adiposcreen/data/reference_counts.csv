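sample,product,n_features,n_ms2,n_id_ge_40,mdc_hits
HDPE 1,refillable drinking bottle,779,203,38,TPP
HDPE 2,yogurt drinking bottle,107,34,7,
HDPE 3,bin liner,614,153,30,TPP
HDPE 4,shower gel bottle,164,50,16,EHDP
LDPE 1,lemon juice bottle,241,66,20,EHDP
LDPE 2,plastic wrap,1833,543,98,TPP
LDPE 3,freezer bag,1603,416,62,TPP
LDPE 4,hair conditioner bottle,1702,544,89,allethrin;TPP
PS 1,yogurt cup,447,96,12,TPP
PS 2,fruit tray,1122,293,44,DPP;TPP
PS 3,vegetable tray,308,63,11,
PS 4,plastic cup,119,30,7,
PP 1,refillable drinking bottle,1365,396,87,TPP
PP 2,yogurt cup,1870,549,93,TPP
PP 3,gummy candy packaging,3159,910,117,TPP
PP 4,handkerchief packaging,1798,519,85,TPP
PP 5,shampoo bottle,268,101,29,
PET 1,soft drink bottle,148,55,18,
PET 2,yogurt cup,179,51,12,
PET 3,oven bag,647,159,30,
PET 4,vegetable tray,695,182,20,
PET 5,shampoo bottle,375,89,11,
PVC 1,plastic wrap,3655,1374,118,
PVC 2,place mat,2426,819,145,DPP;TPP
PVC 3,pond liner,1270,450,91,DINP;TPP
PVC 4,floor covering,2361,868,145,BBP;BPDP;DBP;DEHP;DINP;DPP;EHDP;TBEP;TOCP;TPP
PUR 1,scouring pad,5619,1773,216,EHDP;TPP
PUR 2,kids bath sponge,4521,1182,151,
PUR 3,acoustic foam,6242,2117,224,EHDP;TPP
PUR 4,shower slippers,1035,300,78,EHDP;TPP
PLA 1,yogurt cup,2421,772,52,TPP
PLA 2,vegetable tray,1983,672,40,
PLA 3,coffee cup lid,,,,
PLA 4,coffee cup lid,2575,857,73,
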