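section,category,n,n_text,pct,steps_b,steps_se
type_of_target,70%,3,3,11,4023.82,2927.76
type_of_target,90%,4,4,14,1448.51,2665.40
type_of_target,110%,8,8,29,7152.59,2321.05
type_of_target,130%,14,13,50,6081.24,2050.10
direction,downward,7,7,25,2241.73,2358.08
direction,upward,21,21,75,6403.27,2015.87
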