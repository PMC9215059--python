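cancer,sex,increment,rr,ci_low,ci_high
breast_postmenopausal,F,5,1.12,1.09,1.15
colorectal,F,5,1.05,1.02,1.08
colorectal,M,5,1.08,1.04,1.11
endometrium,F,5,1.50,1.42,1.59
esophagus_adenocarcinoma,F,5,1.48,1.29,1.71
esophagus_adenocarcinoma,M,5,1.56,1.39,1.74
gallbladder,F,5,1.23,1.10,1.39
gallbladder,M,5,1.23,1.10,1.39
kidney,F,5,1.30,1.25,1.36
kidney,M,5,1.30,1.25,1.36
liver,F,5,1.43,1.19,1.70
liver,M,5,1.43,1.19,1.70
mouth_pharynx_larynx,F,5,1.15,1.06,1.24
mouth_pharynx_larynx,M,5,1.15,1.06,1.24
ovary,F,5,1.06,1.02,1.10
pancreas,F,5,1.10,1.04,1.16
pancreas,M,5,1.13,1.04,1.22
prostate_advanced,M,5,1.08,1.03,1.14
stomach_cardia,F,5,1.23,1.07,1.40
stomach_cardia,M,5,1.23,1.07,1.40
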