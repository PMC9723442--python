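structure,metric,plan_s_mean,plan_s_sd,plan_d_mean,plan_d_sd,p
lungs,d_mean,6.61,3.08,6.21,2.96,0.082
lungs,v_pct@5,38.78,17.70,37.06,20.35,0.951
lungs,v_pct@20,8.01,5.07,7.16,4.84,0.017
lungs,v_below_cc@12.5,2574.08,833.09,2598.05,827.63,0.096
lungs,v_below_cc@13.5,2608.84,829.77,2649.26,847.18,0.05
heart,d_mean,3.26,1.63,3.04,1.60,0.333
heart,d_cc@15,11.11,5.09,9.49,3.69,0.049
cord,d_mean,2.25,1.37,2.36,1.42,0.406
cord,d_cc@0.25,9.76,4.77,9.235,4.09,0.506
cord,d_cc@1.2,8.34,4.30,8.15,3.73,0.776
trachea,d_mean,4.21,2.17,3.86,3.15,0.328
trachea,d_max,12.69,8.79,11.51,7.43,0.354
bronchus,d_mean,6.11,4.60,4.96,3.81,0.012
bronchus,d_max,19.82,9.31,16.07,9.14,0.003
trachea_bronchus,d_mean,5.23,3.45,4.44,3.03,0.068
trachea_bronchus,d_max,20.17,9.48,16.51,8.54,0.011
trachea_bronchus,d_cc@4,11.79,6.34,10.47,5.54,0.066
esophagus,d_mean,4.09,1.91,3.33,1.91,0.068
esophagus,d_max,15.95,6.26,12.7,4.94,0.013
esophagus,d_cc@5,9.75,4.04,7.96,3.38,0.064
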