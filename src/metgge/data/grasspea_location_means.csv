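location,name,DTM,BY,SY
L1,"FLRP, Amlaha",115,6.19,2000.71
L2,"IGKV, Raipur",106,11.78,1003.36
L3,"BCKV, Mohanpur",131,6.81,1112.64
L4,"CAU, Imphal",126,6.09,818.25
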