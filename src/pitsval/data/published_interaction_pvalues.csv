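attribute,step,pvalue_diff
mobility,1,0.001
mobility,2,0.917
mobility,3,0.451
mobility,4,0.931
self_care,1,0.278
self_care,2,0.273
self_care,3,0.599
self_care,4,0.999
usual_activities,1,0.968
usual_activities,2,0.611
usual_activities,3,<0.001
usual_activities,4,0.999
pain_discomfort,1,0.739
pain_discomfort,2,0.194
pain_discomfort,3,0.004
pain_discomfort,4,0.999
anxiety_depression,1,0.002
anxiety_depression,2,0.922
anxiety_depression,3,0.710
anxiety_depression,4,0.926
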