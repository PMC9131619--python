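attribute,step,model,coef,pvalue
mobility,1,conditional,0.0879,<0.001
mobility,2,conditional,0.0331,<0.001
mobility,3,conditional,0.1073,<0.001
mobility,4,conditional,0.0134,0.015
self_care,1,conditional,0.0634,<0.001
self_care,2,conditional,0.0062,0.270
self_care,3,conditional,0.0572,<0.001
self_care,4,conditional,0.0170,<0.001
usual_activities,1,conditional,0.0430,<0.001
usual_activities,2,conditional,0.0299,<0.001
usual_activities,3,conditional,0.0987,<0.001
usual_activities,4,conditional,-0.0003,0.956
pain_discomfort,1,conditional,0.0682,<0.001
pain_discomfort,2,conditional,0.0125,0.025
pain_discomfort,3,conditional,0.1244,<0.001
pain_discomfort,4,conditional,0.0297,<0.001
anxiety_depression,1,conditional,0.0649,<0.001
anxiety_depression,2,conditional,0.0486,<0.001
anxiety_depression,3,conditional,0.0565,<0.001
anxiety_depression,4,conditional,0.0384,<0.001
mobility,1,heteroskedastic,0.0726,<0.001
mobility,2,heteroskedastic,0.0340,<0.001
mobility,3,heteroskedastic,0.1097,<0.001
mobility,4,heteroskedastic,0.0059,0.398
self_care,1,heteroskedastic,0.0623,<0.001
self_care,2,heteroskedastic,0.0271,<0.001
self_care,3,heteroskedastic,0.0370,<0.001
self_care,4,heteroskedastic,0.0164,0.003
usual_activities,1,heteroskedastic,0.0588,<0.001
usual_activities,2,heteroskedastic,0.0280,<0.001
usual_activities,3,heteroskedastic,0.1002,<0.001
usual_activities,4,heteroskedastic,-0.0011,0.878
pain_discomfort,1,heteroskedastic,0.0802,<0.001
pain_discomfort,2,heteroskedastic,0.0324,<0.001
pain_discomfort,3,heteroskedastic,0.1034,<0.001
pain_discomfort,4,heteroskedastic,0.0336,<0.001
anxiety_depression,1,heteroskedastic,0.0605,<0.001
anxiety_depression,2,heteroskedastic,0.0444,<0.001
anxiety_depression,3,heteroskedastic,0.0634,<0.001
anxiety_depression,4,heteroskedastic,0.0310,0.003
mobility,1,pc,0.0874,<0.001
mobility,2,pc,0.0232,<0.001
mobility,3,pc,0.1103,<0.001
mobility,4,pc,0.0025,0.662
self_care,1,pc,0.0652,<0.001
self_care,2,pc,0.0276,<0.001
self_care,3,pc,0.0498,<0.001
self_care,4,pc,-0.0002,0.974
usual_activities,1,pc,0.0685,<0.001
usual_activities,2,pc,0.0243,<0.001
usual_activities,3,pc,0.1008,<0.001
usual_activities,4,pc,-0.0046,0.423
pain_discomfort,1,pc,0.0854,<0.001
pain_discomfort,2,pc,0.0325,<0.001
pain_discomfort,3,pc,0.1160,<0.001
pain_discomfort,4,pc,0.0139,0.015
anxiety_depression,1,pc,0.0738,<0.001
anxiety_depression,2,pc,0.0319,<0.001
anxiety_depression,3,pc,0.0623,<0.001
anxiety_depression,4,pc,0.0296,<0.001
mobility,1,bws,0.0261,0.192
mobility,2,bws,0.0478,0.002
mobility,3,bws,0.1078,<0.001
mobility,4,bws,0.0308,0.091
self_care,1,bws,0.0803,<0.001
self_care,2,bws,0.0545,0.028
self_care,3,bws,0.0123,0.602
self_care,4,bws,0.0559,0.001
usual_activities,1,bws,0.0648,0.005
usual_activities,2,bws,-0.0784,0.001
usual_activities,3,bws,0.1129,<0.001
usual_activities,4,bws,0.0312,0.083
pain_discomfort,1,bws,0.0061,0.728
pain_discomfort,2,bws,0.0637,0.010
pain_discomfort,3,bws,0.0856,<0.001
pain_discomfort,4,bws,0.0970,<0.001
anxiety_depression,1,bws,0.0106,0.636
anxiety_depression,2,bws,0.0568,<0.001
anxiety_depression,3,bws,0.0735,<0.001
anxiety_depression,4,bws,0.0575,0.001
mobility,1,taste_class_1,0.0586,<0.001
mobility,2,taste_class_1,0.0290,<0.001
mobility,3,taste_class_1,0.1205,<0.001
mobility,4,taste_class_1,0.0090,0.017
self_care,1,taste_class_1,0.0553,<0.001
self_care,2,taste_class_1,0.0246,<0.001
self_care,3,taste_class_1,0.0630,<0.001
self_care,4,taste_class_1,0.0082,0.030
usual_activities,1,taste_class_1,0.0516,<0.001
usual_activities,2,taste_class_1,0.0297,<0.001
usual_activities,3,taste_class_1,0.1115,<0.001
usual_activities,4,taste_class_1,0.0002,0.967
pain_discomfort,1,taste_class_1,0.0686,<0.001
pain_discomfort,2,taste_class_1,0.0290,<0.001
pain_discomfort,3,taste_class_1,0.1085,<0.001
pain_discomfort,4,taste_class_1,0.0346,<0.001
anxiety_depression,1,taste_class_1,0.0558,<0.001
anxiety_depression,2,taste_class_1,0.0412,<0.001
anxiety_depression,3,taste_class_1,0.0753,<0.001
anxiety_depression,4,taste_class_1,0.0262,<0.001
mobility,1,taste_class_2,0.2954,0.004
mobility,2,taste_class_2,-0.1132,0.348
mobility,3,taste_class_2,0.1903,0.159
mobility,4,taste_class_2,-0.0825,0.518
self_care,1,taste_class_2,-0.2140,0.143
self_care,2,taste_class_2,0.2202,0.127
self_care,3,taste_class_2,-0.0745,0.531
self_care,4,taste_class_2,0.2378,0.048
usual_activities,1,taste_class_2,0.0386,0.794
usual_activities,2,taste_class_2,-0.0073,0.964
usual_activities,3,taste_class_2,-0.0431,0.767
usual_activities,4,taste_class_2,0.0544,0.745
pain_discomfort,1,taste_class_2,0.1218,0.438
pain_discomfort,2,taste_class_2,-0.0898,0.585
pain_discomfort,3,taste_class_2,0.0930,0.575
pain_discomfort,4,taste_class_2,-0.1657,0.341
anxiety_depression,1,taste_class_2,0.3042,0.037
anxiety_depression,2,taste_class_2,0.0648,0.643
anxiety_depression,3,taste_class_2,0.0241,0.885
anxiety_depression,4,taste_class_2,0.1455,0.354
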