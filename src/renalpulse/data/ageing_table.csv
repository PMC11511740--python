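age_group,parameter,mean,sd
20-29,cardiac_output,1.00,0.22
20-29,length,1.00,0.13
20-29,radius,1.00,0.03
20-29,youngs_modulus,1.00,0.13
20-29,thickness,1.00,0.18
20-29,pvr,1.00,0.20
20-29,pvc,1.00,0.25
20-29,sbp_mmhg,120,11
20-29,dbp_mmhg,74,8
30-39,cardiac_output,1.00,0.22
30-39,length,1.08,0.14
30-39,radius,1.03,0.06
30-39,youngs_modulus,1.10,0.18
30-39,thickness,1.10,0.20
30-39,pvr,1.06,0.24
30-39,pvc,0.89,0.24
30-39,sbp_mmhg,119,11
30-39,dbp_mmhg,75,8
40-49,cardiac_output,0.91,0.22
40-49,length,1.16,0.16
40-49,radius,1.04,0.07
40-49,youngs_modulus,1.23,0.16
40-49,thickness,1.12,0.22
40-49,pvr,1.15,0.25
40-49,pvc,0.77,0.21
40-49,sbp_mmhg,121,11
40-49,dbp_mmhg,76,7
50-59,cardiac_output,0.87,0.21
50-59,length,1.22,0.17
50-59,radius,1.07,0.07
50-59,youngs_modulus,1.32,0.25
50-59,thickness,1.25,0.22
50-59,pvr,1.25,0.27
50-59,pvc,0.65,0.18
50-59,sbp_mmhg,124,11
50-59,dbp_mmhg,77,7
60-69,cardiac_output,0.80,0.20
60-69,length,1.32,0.18
60-69,radius,1.15,0.10
60-69,youngs_modulus,1.60,0.35
60-69,thickness,1.51,0.26
60-69,pvr,1.23,0.28
60-69,pvc,0.58,0.15
60-69,sbp_mmhg,126,10
60-69,dbp_mmhg,76,7
70-79,cardiac_output,0.75,0.18
70-79,length,1.40,0.19
70-79,radius,1.18,0.11
70-79,youngs_modulus,2.00,0.45
70-79,thickness,1.75,0.28
70-79,pvr,1.46,0.29
70-79,pvc,0.50,0.11
70-79,sbp_mmhg,127,10
70-79,dbp_mmhg,74,7
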