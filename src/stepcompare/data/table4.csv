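section,category,n,pct,motiv_b,motiv_se,steps_b,steps_se
type_of_target,60%,34,7.2,-0.04,0.11,6932.36,597.06
type_of_target,70%,32,7.2,0.11,0.11,6215.89,605.29
type_of_target,80%,51,10.8,0.21,0.09,5697.40,515.19
type_of_target,90%,100,21.2,0.02,0.07,6356.75,418.57
type_of_target,110%,84,17.8,-0.01,0.08,6078.63,444.95
type_of_target,120%,93,19.7,0.14,0.07,6447.72,424.89
type_of_target,130%,21,4.4,0.20,0.14,6515.59,733.75
type_of_target,140%,60,12.7,0.19,0.09,6965.72,733.75
options_shown,downward_only,159,33.7,0.04,0.06,6573.20,367.93
options_shown,mixed,159,33.7,0.12,0.06,6020.79,366.82
options_shown,upward_only,159,33.7,0.11,0.06,6556.29,368.49
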