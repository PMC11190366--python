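pulse_count,phase_duration_us,phase_amplitude_v,prf_khz,pi_area_mm2,pi_area_se,pi_eft_kvcm,pi_eft_se,ca_area_mm2,ca_area_se,ca_eft_kvcm,ca_eft_se,ah_c,ah_se
50,0.2,1490,200,1.18,0.18,7.65,0.29,1.18,0.28,7.66,0.44,6.48,0.75
50,0.2,1490,50,1.26,0.3,7.54,0.47,1.2,0.11,7.63,0.18,6.42,0.29
50,0.2,1490,20,1.3,0.47,7.47,0.71,1.33,0.36,7.42,0.57,6.1,0.95
50,0.2,1490,2,1.55,0.34,7.09,0.5,1.5,0.35,7.17,0.52,5.69,0.81
50,1,660,200,1.8,0.75,3.41,0.74,1.81,0.82,3.53,0.87,6.43,3.11
50,1,660,50,2.41,1.4,2.93,1.09,2.29,0.95,3.09,0.83,5.49,3.55
50,1,660,20,2.29,0.51,2.97,0.36,2.18,0.41,3.15,0.35,5.33,1.38
50,1,660,2,1.79,0.7,3.52,0.7,1.71,0.66,3.6,0.69,7.23,2.77
50,5,280,50,1.21,0.34,1.85,0.17,1.18,0.53,1.87,0.26,9.66,2.56
50,5,280,20,1.28,0.23,1.81,0.12,1.25,0.3,1.82,0.15,9.21,1.46
50,5,280,2,2.13,0.32,1.44,0.13,2.16,0.84,1.43,0.35,5.73,2.84
50,10,198,20,1.71,1.07,1.11,0.37,1.66,0.88,1.12,0.34,7.13,4.19
50,10,198,2,2.04,1.1,0.99,0.34,2.15,0.82,0.95,0.25,5.06,2.7
100,0.2,1380,200,2.24,0.59,5.83,0.72,2.57,0.43,5.46,0.46,6.6,1.13
100,0.2,1380,50,1.9,0.55,6.25,0.74,1.95,0.23,6.17,0.29,8.41,0.77
100,0.2,1380,20,1.88,0.66,6.28,0.85,1.78,0.24,6.4,0.32,9.06,0.89
100,0.2,1380,2,1.95,0.58,6.2,0.76,2.01,0.53,6.12,0.63,8.3,1.64
100,1,590,200,3.25,1.03,2.14,0.52,2.99,0.4,2.27,0.23,5.68,1.13
100,1,590,50,3.59,1.76,2.02,0.78,3.43,0.59,2.04,0.28,4.6,1.23
100,1,590,20,2.53,0.85,2.26,0.49,2.49,0.61,2.28,0.36,5.76,1.71
100,1,590,2,2.17,0.61,2.5,0.47,2.19,0.77,2.49,0.6,6.96,3.34
100,5,256,50,2.2,0.89,1.23,0.32,2.25,1.1,1.22,0.4,8.39,5.29
100,5,256,20,2.54,1.65,1.13,0.51,2.77,1.52,1.07,0.41,6.63,4.68
100,5,256,2,1.88,0.61,1.08,0.21,1.59,0.59,1.18,0.24,7.84,3.15
100,10,170,20,2.31,0.77,0.76,0.15,2.25,0.57,0.77,0.13,6.59,2.21
100,10,170,2,2.88,0.47,0.65,0.08,2.97,0.61,0.64,0.1,4.48,1.3
200,0.2,880,200,1.5,0.36,4.83,0.44,1.35,0.4,5.01,0.51,11.12,2.23
200,0.2,880,50,1.97,0.34,4.28,0.36,1.69,0.49,4.6,0.57,9.39,2.29
200,0.2,880,20,1.81,0.46,4.46,0.52,1.69,0.57,4.6,0.66,9.42,2.68
200,0.2,880,2,2.07,0.68,4.2,0.7,1.92,0.51,4.35,0.54,8.38,2.05
200,1,356,200,1.46,0.51,2.12,0.37,1.31,0.33,2.23,0.28,11.02,2.71
200,1,356,50,2.19,0.53,1.65,0.27,2.23,0.57,1.64,0.28,5.98,2.01
200,1,356,20,2.09,0.84,1.73,0.41,1.99,0.78,1.69,0.5,7.03,3.36
200,1,356,2,2.4,1.35,1.6,0.52,2.31,0.98,1.62,0.41,5.91,2.72
200,5,190,50,1.63,0.48,1.08,0.19,1.55,0.41,1.11,0.17,13.61,4.25
200,5,190,20,1.87,0.58,0.99,0.19,1.72,0.32,1.04,0.12,11.97,2.63
200,5,140,2,1.77,0.4,0.79,0.09,1.63,0.36,0.82,0.08,7.51,1.42
200,10,132,20,1.89,0.73,0.73,0.15,1.99,0.85,0.71,0.18,11.49,5.6
200,10,100,2,2.24,1.2,0.49,0.21,2.43,1.02,0.46,0.16,4.74,2.89
400,0.2,584,200,1.22,0.15,3.75,0.19,0.97,0.14,4.07,0.18,14.65,1.3
400,0.2,584,50,1.14,0.22,3.85,0.29,0.91,0.28,4.16,0.39,15.32,2.83
400,0.2,584,20,0.98,0.32,4.07,0.43,0.92,0.42,4.15,0.59,15.28,4.37
400,0.2,584,2,1.17,0.44,3.81,0.53,0.82,0.38,4.29,0.54,16.31,4.1
400,1,312,200,1.5,0.36,1.26,0.12,1.51,0.64,1.26,0.21,7.09,2.24
400,1,280,50,0.73,0.47,2.13,0.3,0.9,0.42,2.01,0.25,17.96,4.3
400,1,280,20,1.2,0.11,1.85,0.06,0.92,0.21,2,0.12,17.69,2.05
400,1,280,2,1.77,0.79,1.59,0.33,1.42,0.4,1.74,0.19,13.46,2.77
400,5,122,50,1,0.32,0.88,0.09,0.84,0.35,0.92,0.09,18.79,3.5
400,5,100,20,1.16,0.52,0.71,0.14,0.64,0.47,0.85,0.14,16.17,4.9
400,5,100,2,1.89,0.6,0.55,0.12,1.98,0.52,0.53,0.1,6.25,2.03
400,10,90,20,1.49,0.51,0.57,0.12,1.38,0.68,0.59,0.16,15.74,7.88
400,10,55,2,1.56,0.52,0.33,0.08,1.28,0.54,0.38,0.09,6.41,2.96
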