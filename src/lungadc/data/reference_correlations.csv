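ct_metric,adc_metric,r,p_raw,p_holm
ra950_pct,adc_he3_b1p6,0.90,0.0004,0.008
ra950_pct,adc_xe129_b12,0.85,0.002,0.03
ra950_pct,adc_xe129_b20,0.79,0.006,0.09
ra950_pct,adc_xe129_b30,-0.49,0.68,1.00
ra910_pct,adc_he3_b1p6,0.82,0.004,0.06
ra910_pct,adc_xe129_b12,0.77,0.009,0.11
ra910_pct,adc_xe129_b20,0.78,0.008,0.11
ra910_pct,adc_xe129_b30,-0.06,0.96,0.96
ra856_pct,adc_he3_b1p6,0.67,0.04,0.32
ra856_pct,adc_xe129_b12,0.63,0.05,0.35
ra856_pct,adc_xe129_b20,0.69,0.03,0.27
ra856_pct,adc_xe129_b30,0.30,0.81,1.00
hu15_hu,adc_he3_b1p6,-0.92,0.0002,0.004
hu15_hu,adc_xe129_b12,-0.90,0.0004,0.008
hu15_hu,adc_xe129_b20,-0.86,0.001,0.02
hu15_hu,adc_xe129_b30,0.44,0.71,1.00
visual_score,adc_he3_b1p6,0.79,0.01,0.11
visual_score,adc_xe129_b12,0.76,0.02,0.20
visual_score,adc_xe129_b20,0.66,0.05,0.30
visual_score,adc_xe129_b30,-0.38,0.75,1.00
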