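# Environmental coefficients of the site-index linear predictor
# SI = a0 + sum(a_m * X_m). Variable vocabulary (units):
#   elevation_m (m), aspect_north (cos(aspect*2*pi/360), -), mask_gr (gr),
#   feb_min_temp_c / may_min_temp_c / dec_min_temp_c / feb_mean_temp_c /
#   jul_max_temp_c (degC, 1981-2010 means), jun_pet_mm (mm),
#   may_water_budget_mm / may_water_deficit_mm / jun_water_deficit_mm /
#   jul_water_deficit_mm / may_available_water_mm (mm),
#   swhc_mm / swhc_first_horizon_mm (soil water holding capacity, mm),
#   ph (-), ph_sq (applied to ph^2), cn_ratio (-), cn_ratio_sq (applied to cn_ratio^2),
#   limestone_bedrock / hydromorphic_soils / weakly_hydromorphic_soils /
#   carbonate_rock / brown_soil (0/1 indicators),
#   rock_outcrop / rock_content_40cm (0-10 scores), slope_pct (%),
#   greco_a ... greco_j (ecological-region 0/1 indicators).
species,variable,coefficient
Qu. ro.,feb_mean_temp_c,0.790
Qu. ro.,may_water_deficit_mm,-0.171
Qu. ro.,swhc_mm,0.0282
Qu. ro.,cn_ratio,-0.384
Qu. ro.,limestone_bedrock,-3.358
Qu. ro.,slope_pct,-0.079
Qu. pe.,dec_min_temp_c,4.372
Qu. pe.,jul_water_deficit_mm,-0.354
Qu. pe.,swhc_mm,0.0372
Qu. pe.,cn_ratio,-0.592
Qu. pe.,limestone_bedrock,-11.097
Qu. pe.,greco_d,-7.94
Qu. pu.,swhc_mm,0.0305
Qu. pu.,cn_ratio,-0.167
Qu. pu.,weakly_hydromorphic_soils,2.426
Qu. pu.,brown_soil,0.840
Qu. pu.,greco_b,3.54
Fa. sy.,elevation_m,-0.0083
Fa. sy.,swhc_mm,0.0531
Fa. sy.,cn_ratio,-0.417
Fa. sy.,carbonate_rock,2.625
Fa. sy.,slope_pct,-0.086
Fa. sy.,greco_b,4.64
Pi. pi.,aspect_north,-4.369
Pi. pi.,jun_water_deficit_mm,-0.374
Pi. pi.,cn_ratio,-1.383
Pi. pi.,limestone_bedrock,-32.884
Pi. pi.,weakly_hydromorphic_soils,6.394
Pi. pi.,rock_outcrop,-1.403
Pi. pi.,slope_pct,-0.197
Pi. pi.,greco_j,-9.6825
Pi. sy.,jul_max_temp_c,-3.302
Pi. sy.,ph,-23.311
Pi. sy.,ph_sq,1.359
Pi. sy.,cn_ratio,-4.455
Pi. sy.,cn_ratio_sq,0.066
Pi. sy.,rock_content_40cm,-0.931
Pi. sy.,slope_pct,-0.110
Pi. sy.,greco_c,15.37
Pi. sy.,greco_h,-7.52
Pi. la.,may_available_water_mm,0.275
Pi. la.,cn_ratio,-1.020
Pi. la.,hydromorphic_soils,-8.713
Pi. la.,rock_content_40cm,-2.705
Pi. ni.,mask_gr,-0.549
Pi. ni.,jul_max_temp_c,-3.593
Pi. ni.,cn_ratio,-1.621
Pi. ni.,slope_pct,-0.350
Pi. ha.,elevation_m,-0.0108
Ab. al.,jun_pet_mm,0.446
Ab. al.,swhc_first_horizon_mm,0.5948
Ab. al.,cn_ratio,-0.891
Ab. al.,greco_a,17.83
Ab. al.,greco_h,-11.56
Pi. ab.,aspect_north,-3.705
Pi. ab.,feb_min_temp_c,5.566
Pi. ab.,may_water_budget_mm,0.179
Pi. ab.,swhc_first_horizon_mm,1.2870
Pi. ab.,cn_ratio,-0.938
Pi. ab.,limestone_bedrock,-8.100
Pi. ab.,slope_pct,-0.255
Ps. me.,mask_gr,-0.277
Ps. me.,may_min_temp_c,-4.301
Ps. me.,ph,2.941
Ps. me.,greco_i,-26.72
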