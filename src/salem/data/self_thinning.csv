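# Self-thinning boundary Nmax = exp(p + q*ln(Dg)), Dg in cm, Nmax in stems/ha.
# Published Salem 2.0 estimates (quantile regression on French NFI pure stands).
species,p,q
Qu. ro.,12.60,-1.86
Qu. pe.,13.10,-2.01
Qu. pu.,11.98,-1.66
Fa. sy.,13.99,-2.18
Pi. pi.,12.48,-1.80
Pi. sy.,13.44,-2.03
Pi. la.,10.66,-1.14
Pi. ni.,12.90,-1.81
Pi. ha.,12.83,-1.92
Ab. al.,13.08,-1.86
Pi. ab.,12.88,-1.76
Ps. me.,11.15,-1.30
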