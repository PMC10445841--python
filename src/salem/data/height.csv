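# Height-circumference models:
#   h = 1.3 + (alpha + g1(Dg) + g2(SI)) * (1 - exp(-beta * c130^gamma))
# with h in m, c130 (circumference at 1.30 m) in cm, Dg in cm.
# g1_form: satexp -> a1_1*(1-exp(-a1_2*Dg)); linear -> a1*Dg;
#          quadratic -> a1_1*Dg + a1_2*Dg^2; none.
# g2_form: linear -> a2*SI; quadratic -> a2_1*SI + a2_2*SI^2; log -> a2*ln(SI);
#          satexp -> a2_1*(1-exp(-a2_2*SI)); none.
species,g1_form,g2_form,alpha,a1,a1_1,a1_2,a2,a2_1,a2_2,beta,gamma
Qu. ro.,satexp,linear,-1.3624,,17.9437,0.099,0.4222,,,0.0314,0.8341
Qu. pe.,linear,quadratic,2.1484,0.1692,,,,0.8495,-0.0114,0.0067,1.2896
Qu. pu.,none,quadratic,-3.7295,,,,,5.4023,-0.3118,0.0102,1.1533
Fa. sy.,satexp,quadratic,-5.8023,,15.8848,0.0491,,1.1844,-0.0145,0.0137,1.0219
Pi. pi.,quadratic,quadratic,-5.1515,,0.6972,-0.0058,,0.3408,-0.0026,0.0238,0.9357
Pi. sy.,satexp,linear,-4.4002,,16.303,0.0656,0.1541,,,0.0168,1.0502
Pi. la.,satexp,quadratic,-20.9182,,45.475,0.0645,,0.3808,-0.0037,0.0348,0.7536
Pi. ni.,satexp,none,-6.342,,29.5273,0.0725,,,,0.0224,0.9475
Pi. ha.,satexp,log,-26.1684,,24.4999,0.1001,7.659,,,0.0689,0.6054
Ab. al.,satexp,log,0.8475,,23.0394,0.0411,3.1832,,,0.0075,1.1343
Pi. ab.,satexp,satexp,-30.0783,,45.4929,0.0897,,17.3624,0.0497,0.016,0.9984
Ps. me.,satexp,none,-5.5879,,50.3923,0.0487,,,,0.0355,0.7609
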