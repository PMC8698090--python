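subject_id,role,timepoint,lactate_mmol_l
PH_mean,PH,T0,2.2
PH_mean,PH,T1,8.0
PH_mean,PH,T2,9.5
PH_mean,PH,T3,10.6
PH_mean,PH,T4,4.1
PH_mean,PH,T5,1.8
HH_mean,HH,T0,2.1
HH_mean,HH,T1,5.6
HH_mean,HH,T2,6.3
HH_mean,HH,T3,6.7
HH_mean,HH,T4,2.3
HH_mean,HH,T5,2.3
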