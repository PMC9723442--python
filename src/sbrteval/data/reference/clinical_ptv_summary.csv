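structure,metric,plan_s_mean,plan_s_sd,plan_d_mean,plan_d_sd,p
ptv1,coverage,96.32,1.56,95.58,0.90,0.155
ptv1,d_max,70.21,4.12,72.89,2.06,0.050
ptv1,d_min,46.05,1.18,45.20,1.42,0.023
ptv1,d_mean,56.42,1.50,57.83,1.33,0.032
ptv1,ci,1.20,0.13,1.14,0.08,0.100
ptv1,nci,1.25,0.14,1.19,0.08,0.130
ptv1,hi,1.40,0.08,1.46,0.04,0.050
ptv1,gi,5.76,1.32,5.19,0.81,0.070
ptv2,coverage,96.18,1.53,96.14,1.55,0.962
ptv2,d_max,71.74,3.78,73.38,1.61,0.248
ptv2,d_min,45.86,1.04,46.76,3.83,0.434
ptv2,d_mean,56.82,1.48,58.75,1.47,0.006
ptv2,ci,1.19,0.15,1.23,0.14,0.647
ptv2,nci,1.24,0.14,1.27,0.13,0.596
ptv2,hi,1.43,0.08,1.47,0.03,0.248
ptv2,gi,6.28,1.25,5.29,0.70,0.036
ptv12,coverage,96.42,0.83,95.83,0.65,0.056
ptv12,d_max,73.22,2.22,74.42,1.58,0.184
ptv12,d_min,45.22,0.89,44.74,1.26,0.162
ptv12,d_mean,56.68,1.26,58.17,0.98,0.013
ptv12,ci,1.19,0.13,1.16,0.06,0.422
ptv12,nci,1.24,0.13,1.21,0.06,0.537
ptv12,hi,1.46,0.04,1.49,0.03,0.184
ptv12,gi,5.85,1.03,5.18,0.58,0.031
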