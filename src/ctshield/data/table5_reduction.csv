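scanner_id,angle_deg,factor
CT-1,90,0.036
CT-2,90,0.029
CT-3,90,0.037
CT-4,90,0.023
CT-5,90,0.032
CT-6,90,0.044
CT-7,90,0.024
CT-8,90,0.025
CT-9,90,0.047
CT-10,90,0.031
CT-11,90,0.022
CT-12,90,0.033
CT-13,90,0.022
CT-14,90,0.033
CT-15,90,0.024
CT-16,90,0.047
CT-17,90,0.016
CT-18,90,0.031
CT-1,270,0.036
CT-2,270,0.035
CT-3,270,0.032
CT-4,270,0.039
CT-5,270,0.037
CT-6,270,0.030
CT-7,270,0.017
CT-8,270,0.049
CT-9,270,0.043
CT-10,270,0.020
CT-11,270,0.054
CT-12,270,0.027
CT-13,270,0.043
CT-14,270,0.031
CT-15,270,0.082
CT-16,270,0.073
CT-17,270,0.050
CT-18,270,0.032
CT-1,180,0.218
CT-2,180,0.143
CT-3,180,0.178
CT-4,180,0.193
CT-5,180,0.280
CT-6,180,0.160
CT-7,180,0.253
CT-8,180,0.203
CT-9,180,0.261
CT-10,180,0.252
CT-11,180,0.316
CT-12,180,0.180
CT-13,180,0.188
CT-14,180,0.239
CT-15,180,0.313
CT-16,180,0.320
CT-17,180,0.261
CT-18,180,0.355
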