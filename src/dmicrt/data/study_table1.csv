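subject,sex,bmi_kg_m2,fasting_h,baseline_cgm_mM,auc_cgm_mM_min,auc_dmi_mM_min
1,m,26,11.5,5.61,537.75,157.83
2,m,22,12.0,5.00,442.25,151.79
3,f,22,13.5,5.44,569.07,214.49
4,m,22,11.0,5.89,590.46,155.04
5,f,25,13.0,4.72,457.38,131.56
6,m,25,12.5,5.89,456.73,80.49
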