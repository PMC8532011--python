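source,subgroup,metric,numerator,denominator,printed_pct
abstract,asthma,fulfilling,3194,14644,21.81
abstract,asthma,fulfilling_in_system_6m,797,1194,66.75
abstract,asthma,fulfilling_in_system_12m,1997,2975,67.13
results_table,asthma,fulfilling,3194,14640,21.81
results_table,asthma,all_in_system_6m,2648,7135,37.11
results_table,asthma,fulfilling_in_system_6m,797,1194,66.75
results_table,asthma,all_in_system_12m,6857,18206,37.66
results_table,asthma,fulfilling_in_system_12m,1997,2975,67.13
results_table,ckd,fulfilling,5081,25363,20.03
results_table,ckd,all_in_system_6m,7503,18404,40.77
results_table,ckd,fulfilling_in_system_6m,2178,2918,74.64
results_table,ckd,all_in_system_12m,19558,45994,42.52
results_table,ckd,fulfilling_in_system_12m,5634,7496,75.16
results_table,copd,fulfilling,1456,7579,19.21
results_table,copd,all_in_system_6m,2587,6659,38.85
results_table,copd,fulfilling_in_system_6m,831,1157,71.82
results_table,copd,all_in_system_12m,7026,16941,41.47
results_table,copd,fulfilling_in_system_12m,2179,3009,72.42
results_table,t1d,fulfilling,361,2879,12.54
results_table,t1d,all_in_system_6m,317,1333,23.78
results_table,t1d,fulfilling_in_system_6m,63,112,56.25
results_table,t1d,all_in_system_12m,845,3330,25.38
results_table,t1d,fulfilling_in_system_12m,169,281,60.14
results_table,t2d,fulfilling,7744,56551,13.69
results_table,t2d,all_in_system_6m,10926,30707,35.58
results_table,t2d,fulfilling_in_system_6m,2847,3923,72.57
results_table,t2d,all_in_system_12m,29272,79775,36.69
results_table,t2d,fulfilling_in_system_12m,7177,10065,71.31
prior_study,all_adults,fulfilling,55707,348054,16.01
prior_study,all_adults,all_in_system_6m,39171,123162,31.80
prior_study,all_adults,fulfilling_in_system_6m,10501,15135,69.38
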