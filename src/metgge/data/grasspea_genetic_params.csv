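trait,mean,min,max,gcv,pcv,h2,ga,ga_pct,var_g,var_ge,lsd_5pct,cv_pct
DTM,119,115,122,0.80,0.92,0.76,1.72,1.44,0.92,4.39,6.32,5.3
BY,7.72,5.7,10.51,10.53,12.87,0.67,1.37,17.76,0.66,2.78,0.55,14.86
SY,1233.74,758.32,1740.25,10.42,13.69,0.58,201.72,16.35,16536.58,95370.46,283.3,13.56
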