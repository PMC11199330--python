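label,priority,t_min,t_min_inc,t_max,t_max_inc,s_min,s_min_inc,s_max,s_max_inc
SW,1,1.0,0,,,,,34.00,0
AW,2,3.0,0,,,34.9,0,,
TAW,3,1.0,0,,,34.7,0,34.9,1
IW,4,1.0,0,,,34.0,1,34.7,1
ArW,5,-1.5,1,1.0,1,34.3,1,34.8,1
LW,6,-0.5,1,1.0,1,34.3,1,34.85,1
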