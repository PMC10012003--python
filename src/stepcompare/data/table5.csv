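section,category,n,pct,motiv_b,motiv_se,steps_b,steps_se
type_of_target,0%,10,2.6,-0.07,0.27,3838.82,1160.46
type_of_target,10%,8,2.1,-0.09,0.30,2635.07,1137.18
type_of_target,20%,13,3.4,0.06,0.24,3964.32,922.67
type_of_target,30%,6,1.6,0.18,0.35,3697.40,1277.26
type_of_target,40%,5,1.3,-0.74,0.38,3263.22,1391.01
type_of_target,50%,21,5.4,0.24,0.20,3004.35,874.38
type_of_target,60%,21,5.4,0.39,0.20,3404.35,1127.69
type_of_target,70%,19,4.9,0.50,0.21,3221.15,1130.97
type_of_target,80%,41,10.6,-0.03,0.16,2243.21,901.90
type_of_target,90%,22,5.7,0.10,0.20,3440.08,877.97
type_of_target,100%,9,2.3,0.32,0.29,3337.31,1432.54
type_of_target,110%,14,3.6,0.07,0.24,3598.14,1053.33
type_of_target,120%,55,14.2,-0.09,0.14,3454.85,747.45
type_of_target,130%,9,2.3,0.28,0.29,3221.15,1130.97
type_of_target,140%,11,2.8,-0.11,0.26,2422.84,1127.69
type_of_target,150%,4,1,0.16,0.42,3448.54,1551.14
type_of_target,160%,6,1.6,-0.25,0.35,3891.26,1299.39
type_of_target,170%,10,2.6,0.06,0.27,3345.57,1093.40
type_of_target,180%,5,1.3,0.14,0.38,5536.70,1382.12
type_of_target,190%,6,1.6,0.51,0.35,1878.49,1378.49
type_of_target,200%,5,1.3,0.04,0.38,2900.83,1372.52
type_of_target,110%-199%,18,4.7,-0.12,0.21,3675.08,938.78
type_of_target,200%-999%,41,10.6,0.29,0.16,2949.21,781.46
type_of_target,1000%-1999%,8,2.1,-0.10,0.31,3915.49,1299.92
type_of_target,>2000%,20,5.2,-0.16,0.21,3771.33,962.49
options_shown,fab_below,127,32.8,0.05,0.11,3510.65,667.93
options_shown,fab_between,132,34.1,0.17,0.11,3033.56,669.24
options_shown,fab_above,128,33.1,0.02,0.11,3573.50,668.77
selected_fabricated,no,177,45.7,0.06,0.11,3248.29,653.82
selected_fabricated,yes,210,54.3,0.09,0.10,3463.86,642.90
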