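subject_id,group,adc_he3_b1p6,adc_xe129_b12,adc_xe129_b20,adc_xe129_b30,ra950_pct,ra910_pct,ra856_pct,hu15_hu,visual_score
N1,never-smoker,0.247,0.048,0.048,0.040,,,,,
N2,never-smoker,0.230,0.049,0.049,0.035,,,,,
N3,never-smoker,0.215,0.049,0.049,0.036,,,,,
N4,never-smoker,0.242,0.053,0.053,0.042,,,,,
C1,COPD,0.611,0.096,0.081,,33.33,49.35,67.78,-981,2.35
C2,COPD,0.305,0.057,0.057,,5.26,30.43,67.90,-930,0.16
C3,COPD,0.531,0.087,0.078,,32.07,65.81,85.86,-972,1.55
C4,COPD,0.320,0.058,0.050,,1.53,9.13,36.68,-895,0.43
C5,COPD,0.591,0.095,0.088,,36.83,66.19,84.28,-975,0.89
C6,COPD,0.617,0.095,0.070,,34.25,60.48,79.03,-977,
C7,COPD,0.504,0.085,0.079,0.064,12.12,31.56,60.64,-943,0.83
C8,COPD,0.474,0.083,0.072,0.055,16.77,40.14,66.75,-954,1.40
C9,COPD,0.283,0.056,0.046,,2.12,13.38,47.61,-907,0.34
C10,COPD,0.526,0.092,0.076,0.052,13.22,29.00,53.02,-945,1.49
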