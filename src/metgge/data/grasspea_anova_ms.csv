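trait,source,df,mean_square,pct_contribution
DTM,environment,3,13223.81,82.41
DTM,genotype,63,794.30,4.95
DTM,interaction,189,2028.26,12.64
BY,environment,3,814.64,86.02
BY,genotype,63,55.59,5.87
BY,interaction,189,76.80,8.11
SY,environment,3,28142885.31,78.34
SY,genotype,63,2399725.22,6.68
SY,interaction,189,5381419.73,14.98
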