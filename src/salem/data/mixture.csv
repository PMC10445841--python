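# Directional mixture-effect coefficients: effect of `companion` on the growth
# of `target`.  u = s0*(1-x) when s1 is empty (average-effect form), and
# u = (s0 + s1*SI_target)*(1-x) when s1 is present (site-interaction form).
# Only directed relations with at least one significant coefficient are listed;
# any pair absent from this file carries a neutral effect (u = 0).
# Note: the published coefficient table prints the Pi. ni. / Pi. sy. relation as
# two "s0" rows (1.419 and -0.017); the second row is read here as the
# site-index interaction s1 = -0.017 (the coefficient-naming is taken as a
# typesetting slip; both printed values are retained).
target,companion,s0,s1
Qu. ro.,Pi. pi.,0.692,
Qu. ro.,Pi. sy.,0.374,
Qu. pe.,Qu. ro.,0.215,
Qu. pe.,Fa. sy.,0.618,-0.022
Qu. pe.,Pi. sy.,0.253,
Qu. pu.,Qu. ro.,2.133,-0.323
Fa. sy.,Qu. ro.,2.299,-0.058
Fa. sy.,Qu. pe.,0.833,-0.019
Fa. sy.,Pi. sy.,0.714,
Fa. sy.,Ab. al.,0.544,
Fa. sy.,Pi. ab.,0.435,
Pi. pi.,Qu. ro.,0.384,
Pi. sy.,Qu. pu.,0.902,
Pi. sy.,Fa. sy.,0.110,-0.012
Pi. sy.,Pi. la.,1.025,
Pi. sy.,Ab. al.,-0.406,
Pi. ni.,Pi. sy.,1.419,-0.017
Ab. al.,Qu. pe.,2.080,-0.060
Ab. al.,Fa. sy.,0.996,-0.032
Ab. al.,Pi. sy.,0.991,
Ab. al.,Pi. ab.,0.910,-0.024
Ab. al.,Ps. me.,2.371,-0.060
Pi. ab.,Pi. sy.,0.417,
Pi. ab.,Ab. al.,1.792,-0.024
Pi. ab.,Ps. me.,1.176,-0.016
Ps. me.,Ab. al.,0.259,
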