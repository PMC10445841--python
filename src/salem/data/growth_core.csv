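# Pure-stand basal-area-increment model: BAI5 = SI * f2(DI) * f3(Dg), in m2/ha per 5 years (under bark).
# equation_form: eq3 -> f2(DI) = DI^b ; eq4 -> f2(DI) = (1+b)*DI / (b+DI).
# f3(Dg) = (exp(c1*Dg) + c2) / (1 + c2).
# a0 is the site-index intercept of the f1 linear predictor (see growth_site_terms.csv).
species,equation_form,a0,b,c1,c2
Qu. ro.,eq3,22.00,0.588,-0.078,0.098
Qu. pe.,eq3,55.87,0.625,-0.111,0.063
Qu. pu.,eq3,6.95,0.631,-0.080,0.345
Fa. sy.,eq3,39.71,0.585,-0.083,0.073
Pi. pi.,eq3,117.64,0.699,-0.106,0.051
Pi. sy.,eq3,291.25,0.591,-0.146,0.048
Pi. la.,eq3,73.41,0.603,-0.165,0.092
Pi. ni.,eq3,199.47,0.693,-0.158,0.058
Pi. ha.,eq3,19.30,0.600,-0.118,0.169
Ab. al.,eq4,-7.43,0.234,-0.077,0.119
Pi. ab.,eq3,94.06,0.637,-0.129,0.104
Ps. me.,eq4,71.36,0.450,-0.157,0.180
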