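site,sex,pif_pct,pif_low_pct,pif_high_pct,cost_musd,attributable_musd,attributable_low_musd,attributable_high_musd
breast_any,F,2.70,2.08,3.32,620.39,16.77,12.89,20.60
colorectal,F,2.83,1.19,4.45,220.93,6.26,2.63,9.83
colorectal,M,3.58,1.92,5.17,228.91,8.19,4.39,11.83
colorectal,T,3.21,1.56,4.81,449.84,14.44,7.02,21.66
endometrium,F,24.60,23.07,26.10,36.62,9.01,8.45,9.56
esophagus_any,F,2.28,2.06,2.49,9.76,0.22,0.20,0.24
esophagus_any,M,1.88,1.70,2.04,34.56,0.65,0.59,0.71
esophagus_any,T,1.96,1.78,2.14,44.32,0.87,0.79,0.95
gallbladder,F,12.28,10.20,14.43,2.31,0.28,0.24,0.33
gallbladder,M,9.86,7.66,11.99,1.14,0.11,0.09,0.14
gallbladder,T,11.48,9.36,13.62,3.45,0.40,0.32,0.47
kidney,F,15.67,14.13,17.19,8.71,1.36,1.23,1.50
kidney,M,12.57,11.00,14.11,12.88,1.62,1.42,1.82
kidney,T,13.82,12.26,15.35,21.59,2.98,2.65,3.31
liver,F,21.61,19.01,24.20,5.48,1.18,1.04,1.33
liver,M,17.32,14.60,20.06,8.79,1.52,1.28,1.76
liver,T,18.97,16.30,21.65,14.27,2.71,2.32,3.09
mouth_pharynx_larynx,F,8.21,6.37,10.07,20.42,1.68,1.30,2.06
mouth_pharynx_larynx,M,6.57,4.68,8.40,92.01,6.04,4.31,7.73
mouth_pharynx_larynx,T,6.87,4.99,8.70,112.43,7.72,5.61,9.78
ovary,F,3.17,1.46,4.87,61.78,1.96,0.90,3.01
pancreas,F,5.57,3.79,7.25,20.77,1.16,0.79,1.51
pancreas,M,5.72,3.79,7.58,20.08,1.15,0.76,1.52
pancreas,T,5.65,3.79,7.41,40.85,2.31,1.55,3.03
prostate_any,M,0.91,0.49,1.31,352.87,3.21,1.72,4.63
stomach_any,F,0.47,0.38,0.56,26.58,0.13,0.10,0.15
stomach_any,M,0.56,0.43,0.70,47.55,0.27,0.20,0.33
stomach_any,T,0.53,0.41,0.65,74.13,0.39,0.31,0.48
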