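probe_name,vessel_id,axial_fraction
renal_main_l,renal_main_l,0.5
renal_main_r,renal_main_r,0.5
renal_seg_l1,renal_seg_l1,0.5
renal_seg_l2,renal_seg_l2,0.5
renal_seg_l3,renal_seg_l3,0.5
renal_seg_l4,renal_seg_l4,0.5
renal_seg_l5,renal_seg_l5,0.5
renal_seg_r1,renal_seg_r1,0.5
renal_seg_r2,renal_seg_r2,0.5
renal_seg_r3,renal_seg_r3,0.5
renal_seg_r4,renal_seg_r4,0.5
renal_seg_r5,renal_seg_r5,0.5
brachial,brachial_l,0.5
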