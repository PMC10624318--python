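bap,kin,naa,iba,cfr_mean,cfr_se,cfw_mean,cfw_se
0,0,0,0,0.00,0.000,0.00,0.000
0.5,0,0.05,0,46.43,8.502,1.46,0.054
0.5,0,0.5,0,75.00,7.715,1.47,0.026
0.5,0,0,0.05,53.57,12.711,1.24,0.116
0.5,0,0,0.5,64.29,5.051,1.21,0.076
1,0,0.1,0,75.00,7.715,1.43,0.036
1,0,1,0,85.71,5.051,1.50,0.039
1,0,0,0.1,78.57,3.571,1.52,0.079
1,0,0,1,89.29,5.051,1.67,0.026
1.5,0,0.15,0,67.86,4.611,1.24,0.094
1.5,0,1.5,0,89.29,5.051,1.65,0.061
1.5,0,0,0.15,85.71,5.051,1.60,0.046
1.5,0,0,1.5,92.86,4.611,1.79,0.035
2,0,0.2,0,71.43,12.711,1.31,0.220
2,0,2,0,67.86,13.041,1.12,0.212
2,0,0,0.2,71.43,12.711,1.12,0.202
2,0,0,2,89.29,5.051,1.69,0.054
0,0.5,0.05,0,53.57,10.102,1.25,0.212
0,0.5,0.5,0,82.14,4.611,1.48,0.052
0,0.5,0,0.05,64.29,12.023,1.27,0.228
0,0.5,0,0.5,75.00,7.715,1.39,0.032
0,1,0.1,0,75.00,5.455,1.46,0.059
0,1,1,0,82.14,4.611,1.59,0.077
0,1,0,0.1,67.86,7.143,1.51,0.069
0,1,0,1,57.14,10.514,1.17,0.199
0,1.5,0.15,0,78.57,3.571,1.38,0.084
0,1.5,1.5,0,53.57,10.102,1.10,0.192
0,1.5,0,0.15,75.00,5.455,1.60,0.070
0,1.5,0,1.5,82.14,4.611,1.58,0.014
0,2,0.2,0,57.14,10.514,1.20,0.208
0,2,2,0,85.71,7.435,1.53,0.008
0,2,0,0.2,42.86,11.845,1.08,0.278
0,2,0,2,71.43,12.711,1.34,0.225
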