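scanner_id,angle_deg,distance_cm,dose_1m_mSv,detected
CT-1,0,227,46.74,True
CT-1,45,225,82.42,True
CT-1,90,225,3.49,True
CT-1,135,383,97.47,True
CT-1,180,435,21.29,True
CT-1,225,277,95.22,True
CT-1,270,300,3.56,True
CT-1,315,198,94.23,True
CT-2,0,217,53.80,True
CT-2,45,238,106.77,True
CT-2,90,214,4.81,True
CT-2,135,412,166.77,True
CT-2,180,417,23.91,True
CT-2,225,239,91.05,True
CT-2,270,300,5.90,True
CT-2,315,210,107.49,True
CT-3,0,190,16.08,True
CT-3,45,300,12.78,True
CT-3,90,275,1.82,True
CT-3,135,383,48.55,True
CT-3,180,494,8.66,True
CT-3,225,233,26.49,True
CT-3,270,250,1.53,True
CT-3,315,300,5.58,True
CT-4,0,235,8.31,True
CT-4,45,235,,False
CT-4,90,360,0.26,True
CT-4,135,355,11.09,True
CT-4,180,391,2.14,True
CT-4,225,329,,False
CT-4,270,214,0.44,True
CT-4,315,209,5.90,True
CT-5,0,209,24.09,True
CT-5,45,200,18.88,True
CT-5,90,198,1.74,True
CT-5,135,296,48.67,True
CT-5,180,473,15.29,True
CT-5,225,251,54.68,True
CT-5,270,180,2.02,True
CT-5,315,222,16.61,True
CT-6,0,242,27.09,True
CT-6,45,200,42.24,True
CT-6,90,297,1.85,True
CT-6,135,360,37.58,True
CT-6,180,362,6.75,True
CT-6,225,293,31.29,True
CT-6,270,233,1.25,True
CT-6,315,198,22.29,True
CT-7,0,210,35.06,True
CT-7,45,258,14.71,True
CT-7,90,175,1.70,True
CT-7,135,270,71.41,True
CT-7,180,390,18.10,True
CT-7,225,290,44.11,True
CT-7,270,215,1.22,True
CT-7,315,180,7.71,True
CT-8,0,249,37.23,True
CT-8,45,197,34.81,True
CT-8,90,200,2.36,True
CT-8,135,180,52.96,True
CT-8,180,366,18.89,True
CT-8,225,340,92.88,True
CT-8,270,348,4.54,True
CT-8,315,255,67.27,True
CT-9,0,256,2.23,True
CT-9,45,215,0.88,True
CT-9,90,158,0.26,True
CT-9,135,233,5.54,True
CT-9,180,380,1.44,True
CT-9,225,338,5.08,True
CT-9,270,185,0.24,True
CT-9,315,280,0.55,True
CT-10,0,238,32.83,True
CT-10,45,280,27.64,True
CT-10,90,203,2.74,True
CT-10,135,266,66.44,True
CT-10,180,334,21.92,True
CT-10,225,186,87.01,True
CT-10,270,180,1.72,True
CT-10,315,190,19.39,True
CT-11,0,241,48.50,True
CT-11,45,220,65.12,True
CT-11,90,302,2.51,True
CT-11,135,383,85.30,True
CT-11,180,417,35.65,True
CT-11,225,371,112.66,True
CT-11,270,267,6.06,True
CT-11,315,260,66.86,True
CT-12,0,229,47.93,True
CT-12,45,296,43.98,True
CT-12,90,221,5.59,True
CT-12,135,276,170.67,True
CT-12,180,439,30.64,True
CT-12,225,357,147.90,True
CT-12,270,296,4.64,True
CT-12,315,292,52.57,True
CT-13,0,230,29.94,True
CT-13,45,270,67.25,True
CT-13,90,200,1.46,True
CT-13,135,315,55.12,True
CT-13,180,390,12.62,True
CT-13,225,400,56.56,True
CT-13,270,255,2.89,True
CT-13,315,270,62.37,True
CT-14,0,225,12.73,True
CT-14,45,175,10.14,True
CT-14,90,160,0.88,True
CT-14,135,225,26.83,True
CT-14,180,360,6.42,True
CT-14,225,470,26.73,True
CT-14,270,185,0.82,True
CT-14,315,275,18.00,True
CT-15,0,230,33.59,True
CT-15,45,194,29.30,True
CT-15,90,213,1.13,True
CT-15,135,193,18.87,True
CT-15,180,390,14.91,True
CT-15,225,403,47.59,True
CT-15,270,240,3.92,True
CT-15,315,223,36.55,True
CT-16,0,210,32.02,True
CT-16,45,300,32.27,True
CT-16,90,248,2.24,True
CT-16,135,360,44.39,True
CT-16,180,420,15.26,True
CT-16,225,458,47.72,True
CT-16,270,330,3.48,True
CT-16,315,300,24.66,True
CT-17,0,240,24.13,True
CT-17,45,336,22.06,True
CT-17,90,296,0.79,True
CT-17,135,424,50.44,True
CT-17,180,416,13.18,True
CT-17,225,456,48.76,True
CT-17,270,320,2.51,True
CT-17,315,344,28.10,True
CT-18,0,230,26.79,True
CT-18,45,185,16.94,True
CT-18,90,210,1.39,True
CT-18,135,255,45.19,True
CT-18,180,420,16.05,True
CT-18,225,360,30.26,True
CT-18,270,210,1.46,True
CT-18,315,190,18.81,True
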