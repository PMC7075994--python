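subpopulation,alias_of,nesting_share,s1,s2,s3,b1,b2,b3,b4,transient,clutch_size,ecf,eggs_per_season,emergence_success,water_success,survival_to_water,harvest_rate,sex_ratio,clutch_size_sd,ecf_sd,s3_ci_low,s3_ci_high,transient_ci_low,transient_ci_high
costa_rica,,0.222,0.063,0.500,0.788,0.005,0.272,0.540,0.681,0.131,66.0,6.1,403,0.40,0.775,0.31,0.010,0.840,16.6,3.1,0.750,0.807,0.157,0.346
mexico,,0.754,0.063,0.500,0.705,0.003,0.169,0.379,0.550,0.279,66.0,5.9,390,,,0.47,0.042,0.840,16.5,2.2,0.675,0.741,0.106,0.560
nicaragua,costa_rica,0.024,,,,,,,,,,,,,,,,,,,,,,
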