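name,cid,abbreviation
benzyl butyl phthalate,2347,BBP
tert-butylphenyl diphenyl phosphate,95120,BPDP
dibutyl phthalate,3026,DBP
bis(2-ethylhexyl) phthalate,8343,DEHP
di-iso-nonyl phthalate,590836,DINP
diphenyl phosphate,24313,DPP
2-ethylhexyl diphenyl phosphate,14716,EHDP
tris(2-butoxyethyl) phosphate,6540,TBEP
tri-o-cresyl phosphate,6527,TOCP
triphenyl phosphate,8289,TPP
allethrin,11442,allethrin
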