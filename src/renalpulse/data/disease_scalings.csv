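stage,parameter,vessel_class,multiplier,lit_mean,lit_sd
Early.D,viscosity,,1.10,1.07,0.26
Early.D,cardiac_output,,0.85,0.85,0.10
Early.D,radius,default,0.95,,
Early.D,radius,abdominal_aorta,0.95,0.93,0.02
Early.D,radius,carotid,0.95,0.93,0.02
Early.D,radius,radial,0.95,0.96,0.02
Early.D,youngs_modulus,default,1.10,,
Early.D,youngs_modulus,ascending_aorta,1.10,1.15,
Early.D,youngs_modulus,radial,1.10,1.06,0.30
Early.D,youngs_modulus,brachial,1.10,1.10,0.28
Early.D,youngs_modulus,carotid,1.10,1.18,0.64
Early.D,thickness,default,1.15,,
Early.D,thickness,descending_aorta,1.15,1.21,0.23
Early.D,thickness,carotid,1.15,1.05,0.20
Early.D,pvr,,1.20,1.12,0.26
Early.D,pvc,,0.82,0.82,0.25
Severe.D,viscosity,,1.20,1.23,0.30
Severe.D,cardiac_output,,0.70,0.72,0.05
Severe.D,radius,default,0.90,,
Severe.D,radius,abdominal_aorta,0.90,0.91,0.02
Severe.D,radius,radial,0.90,0.96,0.02
Severe.D,youngs_modulus,default,1.30,,
Severe.D,youngs_modulus,ascending_aorta,1.30,1.29,
Severe.D,thickness,default,1.28,,
Severe.D,thickness,carotid,1.28,1.40,0.03
Severe.D,pvr,,1.40,1.40,0.33
Severe.D,pvc,,0.80,0.80,0.26
Early.H,viscosity,,1.00,1.02,0.09
Early.H,cardiac_output,,1.15,1.15,
Early.H,radius,default,0.98,,
Early.H,radius,ascending_aorta,0.95,0.96,0.02
Early.H,radius,renal,0.98,1.00,0.13
Early.H,radius,carotid,0.98,0.99,
Early.H,youngs_modulus,default,1.20,,
Early.H,youngs_modulus,carotid,1.20,1.21,0.54
Early.H,thickness,default,1.00,,
Early.H,thickness,descending_aorta,1.00,1.00,0.10
Early.H,thickness,carotid,1.00,1.02,0.22
Early.H,pvr,,1.15,1.17,0.27
Early.H,pvc,,0.86,0.86,0.25
Severe.H,viscosity,,1.00,1.06,0.12
Severe.H,cardiac_output,,1.00,,
Severe.H,radius,default,0.95,,
Severe.H,radius,ascending_aorta,0.93,0.92,0.02
Severe.H,youngs_modulus,default,1.40,,
Severe.H,youngs_modulus,carotid,1.40,1.51,0.98
Severe.H,thickness,default,1.05,,
Severe.H,thickness,aorta,1.10,,
Severe.H,pvr,,1.35,1.33,0.32
Severe.H,pvc,,0.70,0.67,0.02
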