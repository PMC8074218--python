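run_id,ey,ey_sd,tpc_total,tpc_total_sd,tpc_surface,tpc_surface_sd,tc,tc_sd,tc_sd_raw,ee,ee_sd,lc,lc_sd,moisture,moisture_sd,aw,aw_sd,color_L,color_L_sd,color_a,color_a_sd,color_b,color_b_sd
1,32.48,1.36,6.93,0.16,0.32,0.02,5.50,0.09,,72.64,1.88,6.60,0.17,3.35,0.23,0.44,0.00,76.78,0.96,2.72,0.23,22.89,0.31
2,35.69,0.53,18.24,0.03,0.56,0.00,14.46,0.25,,76.58,0.16,17.67,0.04,3.67,0.03,0.37,0.00,71.08,1.40,4.11,0.27,27.13,0.33
3,42.62,0.49,6.62,0.09,0.32,0.04,5.26,0.07,,69.33,1.10,6.30,0.10,4.22,0.02,0.41,0.00,75.01,1.26,3.02,0.15,24.38,0.14
4,48.92,0.94,17.67,0.06,0.58,0.03,14.02,0.37,,74.09,0.17,17.10,0.04,4.30,0.09,0.40,0.00,70.35,0.70,4.22,0.08,27.20,0.22
5,34.29,0.85,4.10,0.11,0.26,0.00,3.200,,0.1.2,70.05,1.93,3.84,0.11,4.11,0.06,0.36,0.00,78.98,0.46,2.27,0.04,21.48,0.13
6,33.96,0.81,19.33,0.04,1.58,0.02,15.34,0.29,,68.03,0.22,17.76,0.06,4.19,0.12,0.38,0.00,69.18,0.17,4.71,0.03,28.38,0.05
7,39.75,0.87,13.14,0.03,0.35,0.02,10.29,0.06,,76.74,0.03,12.79,0.00,4.070,0.24,0.34,0.00,71.03,0.08,4.24,0.06,27.37,0.04
8,43.57,1.18,12.72,0.13,0.38,0.01,9.71,,0.1.5,74.06,0.82,12.34,0.14,3.96,0.14,0.37,0.00,70.97,1.09,4.13,0.20,27.55,0.41
9,38.42,0.45,12.55,0.13,0.36,0.05,9.95,0.27,,73.17,0.46,12.20,0.08,4.34,0.07,0.38,0.00,70.56,0.49,4.28,0.05,27.65,0.11
10,37.80,0.63,12.63,0.04,0.35,0.01,9.85,0.16,,73.67,0.22,12.28,0.05,3.97,0.13,0.35,0.00,70.01,0.61,4.45,0.16,28.02,0.37
11,38.81,0.82,12.69,0.07,0.37,0.03,9.86,0.14,,73.92,0.35,12.32,0.06,3.83,0.66,0.36,0.00,70.57,0.16,4.35,0.03,27.96,0.10
12,38.63,1.25,12.68,0.72,0.36,0.00,9.88,0.15,,73.94,0.42,12.32,0.72,3.32,0.12,0.35,0.00,70.03,0.80,4.29,0.09,27.56,0.04
13,39.42,1.85,12.72,0.11,0.37,0.00,9.79,0.14,,74.05,0.63,12.34,0.11,3.49,0.01,0.34,0.00,69.99,0.24,4.40,0.05,28.06,0.18
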