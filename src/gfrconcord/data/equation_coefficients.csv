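id,marker,parameter,value
ckdepi2009_cr,cr,intercept,141
ckdepi2009_cr,cr,kappa_female,0.7
ckdepi2009_cr,cr,kappa_male,0.9
ckdepi2009_cr,cr,alpha_female,-0.329
ckdepi2009_cr,cr,alpha_male,-0.411
ckdepi2009_cr,cr,beta,-1.209
ckdepi2009_cr,cr,age_factor,0.993
ckdepi2009_cr,cr,female_factor,1.018
ckdepi2021_cr,cr,intercept,142
ckdepi2021_cr,cr,kappa_female,0.7
ckdepi2021_cr,cr,kappa_male,0.9
ckdepi2021_cr,cr,alpha_female,-0.241
ckdepi2021_cr,cr,alpha_male,-0.302
ckdepi2021_cr,cr,beta,-1.2
ckdepi2021_cr,cr,age_factor,0.9938
ckdepi2021_cr,cr,female_factor,1.012
ckdepi2012_cys,cys,intercept,133
ckdepi2012_cys,cys,kappa,0.8
ckdepi2012_cys,cys,alpha,-0.499
ckdepi2012_cys,cys,beta,-1.328
ckdepi2012_cys,cys,age_factor,0.996
ckdepi2012_cys,cys,female_factor,0.932
ckdepi2012_crcys,cr+cys,intercept,135
ckdepi2012_crcys,cr+cys,kappa_cr_female,0.7
ckdepi2012_crcys,cr+cys,kappa_cr_male,0.9
ckdepi2012_crcys,cr+cys,alpha_cr_female,-0.248
ckdepi2012_crcys,cr+cys,alpha_cr_male,-0.207
ckdepi2012_crcys,cr+cys,beta_cr,-0.601
ckdepi2012_crcys,cr+cys,kappa_cys,0.8
ckdepi2012_crcys,cr+cys,alpha_cys,-0.375
ckdepi2012_crcys,cr+cys,beta_cys,-0.711
ckdepi2012_crcys,cr+cys,age_factor,0.995
ckdepi2012_crcys,cr+cys,female_factor,0.969
ekfc2021_cr,cr,intercept,107.3
ekfc2021_cr,cr,alpha_low,0.322
ekfc2021_cr,cr,alpha_high,1.132
ekfc2021_cr,cr,age_decay,0.99
ekfc2021_cr,cr,age_knot,40
ekfc2021_cr,cr,q_female,0.7
ekfc2021_cr,cr,q_male,0.9
ekfc2023_cys,cys,intercept,107.3
ekfc2023_cys,cys,alpha_low,0.322
ekfc2023_cys,cys,alpha_high,1.132
ekfc2023_cys,cys,age_decay,0.99
ekfc2023_cys,cys,age_knot,40
ekfc2023_cys,cys,q_base,0.83
ekfc2023_cys,cys,q_age_slope,0.005
ekfc2023_cys,cys,q_age_knot,50
cockcroft_gault,cr,age_offset,140
cockcroft_gault,cr,denominator,72
cockcroft_gault,cr,female_factor,0.85
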