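# Bark proportion (share of over-bark basal area) as a function of dbh (cm).
# form: a_b_cinv -> a + b*dbh + c/dbh ; a_b -> a + b*dbh ; a_b_c2 -> a + b*dbh + c*dbh^2.
# Predictions are clamped to the [10 cm, max_dbh] calibration range.
# "Quercus spp." was fitted to undistinguished oak data and serves
# Qu. ro., Qu. pe. and Qu. pu.; Pi. ha. uses the Pi. sy. model (no bark data
# exist for it and the two species have very similar bark proportions).
model,form,a,b,c,max_dbh
Quercus spp.,a_b_cinv,0.1426,-0.000496,1.028,80
Fa. sy.,a_b_cinv,0.0502,-0.000042,0.162,80
Pi. pi.,a_b_cinv,0.4792,-0.003252,-0.765,80
Pi. sy.,a_b,0.2711,-0.00128,,60
Pi. la.,a_b_c2,0.2948,-0.000679,-1.21e-5,60
Pi. ni.,a_b_cinv,0.3311,-0.001611,-0.263,60
Ab. al.,a_b_cinv,0.1084,-0.000139,0.148,80
Pi. ab.,a_b_cinv,0.0864,0.000151,0.522,80
Ps. me.,a_b_cinv,0.1659,-0.001409,3.0e-5,60
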