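structure,metric,plan_s_mean,plan_s_sd,plan_d_mean,plan_d_sd,p
ptv1,eud,94.18,1.67,95.18,0.93,0.229
ptv2,eud,94.58,1.91,96.97,1.83,0.105
ptv12,eud,94.41,1.51,95.55,0.67,0.140
lungs,eud,9.21,4.12,8.61,3.97,0.049
heart,eud,6.21,3.15,4.98,2.38,0.022
cord,eud,8.80,4.48,8.02,3.64,0.471
esophagus,eud,13.33,5.58,9.72,4.30,0.099
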