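# SYNTHETIC example demographic table (approximate mid-2000s Japanese
# 60+ age structure, rounded by hand for demos and tests).  Not census
# data: supply a real reference table for any substantive analysis.
# sex: 1=male, 2=female; strata are half-open [age_lo, age_hi).
sex,age_lo,age_hi,proportion
1,60,65,0.105
1,65,70,0.095
1,70,75,0.085
1,75,80,0.070
1,80,85,0.055
1,85,95,0.040
2,60,65,0.115
2,65,70,0.105
2,70,75,0.100
2,75,80,0.090
2,80,85,0.075
2,85,95,0.065
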