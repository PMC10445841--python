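# Within-stand dbh standard deviation as a Chapman-Richards function of Dg:
# sigma = alpha * (1 - exp(-gamma*Dg))^beta, all diameters in cm.
species,alpha,gamma,beta
Qu. ro.,11.43876,0.09017,3.33197
Qu. pe.,10.97643,0.08640,3.22690
Qu. pu.,7.72100,0.18849,8.74034
Fa. sy.,12.24093,0.07743,2.85483
Pi. pi.,6.65825,0.08697,2.14814
Pi. sy.,8.56996,0.08513,2.10282
Pi. la.,7.57343,0.07817,2.57583
Pi. ni.,6.35432,0.16440,5.72509
Pi. ha.,8.95631,0.18881,9.68719
Ab. al.,13.25233,0.05094,1.76612
Pi. ab.,30.18095,0.00754,0.94366
Ps. me.,7.38019,0.12265,4.59548
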