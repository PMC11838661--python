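name,chemical_shift_ppm,t1_gm_ms,t1_wm_ms,t1_csf_ms,t2_gm_ms,t2_wm_ms,t2_csf_ms,n_deuterons,label_loss_fraction
water,4.8,358,328,510,36,34,90,1,0.0
glc,3.9,80,80,80,34,34,34,2,0.0
glx,2.4,165,165,165,33,33,33,1,0.4
lac,1.3,150,150,150,40,40,40,2,0.0
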