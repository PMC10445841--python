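# Commercial volume (dm3, bole to a 7 cm small-end diameter) from dbh (cm)
# and total height (m): v = beta1*h/dbh + (beta2 + beta3*dbh)*pi*dbh^2*h/40.
# Empty cells mean the coefficient was dropped (non-significant) -> 0.
# "Qu. sp." was fitted to undistinguished oak data and serves Qu. pu.
model,beta1,beta2,beta3
Qu. ro.,,0.5057,
Qu. pe.,-4.438,0.5455,-1.397e-3
Qu. sp.,-3.319,0.5664,-1.778e-3
Fa. sy.,-4.498,0.5107,-1.332e-3
Pi. pi.,-1.712,0.5130,-1.124e-3
Pi. sy.,-2.247,0.4985,-1.212e-3
Pi. la.,,0.5215,-1.271e-3
Pi. ni.,-8.427,0.5857,-2.748e-3
Pi. ha.,,0.5258,-2.300e-3
Ab. al.,-4.523,0.6011,-2.243e-3
Pi. ab.,-8.666,0.5839,-2.679e-3
Ps. me.,-7.150,0.5431,-2.951e-3
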