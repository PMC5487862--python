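scanner_id,manufacturer,model,detector_rows,max_beam_width_cm,dlp_head_mGycm,dlp_body_mGycm,workload_head_mAs,workload_body_mAs,scans_head,scans_body,head_dlp_ratio_pct
CT-1,Toshiba,Aquilion CX,64,3.2,147415,282204,,,146,290,34.3
CT-2,Toshiba,Aquilion 64,64,3.2,171884,328855,,,182,344,34.3
CT-3,Toshiba,Aquilion 64,64,3.2,31780,88807,84194,225274,50,153,26.4
CT-4,Toshiba,Prime 80,80,4.0,45850,10228,76479,29331,60,46,81.8
CT-5,Toshiba,Aquilion 64,64,3.2,64314,176263,202591,476192,79,249,26.7
CT-6,Hitachi,Scenaria,64,4.0,64478,107404,181766,250897,108,99,37.5
CT-7,GE,VCT,64,4.0,27276,322042,148788,648442,32,320,7.8
CT-8,Hitachi,Scenaria,64,4.0,86603,176837,354165,503669,95,237,32.9
CT-9,Hitachi,Eclos,16,2.0,5369,10597,39907,58920,8,18,33.6
CT-10,GE,VCT,64,4.0,39567,183156,113500,603387,33,223,17.8
CT-11,Siemens,Definition Flash,128,3.84,27624,340808,38484,1553913,15,464,7.5
CT-12,GE,VCT,64,4.0,14316,428014,49664,1422999,17,480,3.2
CT-13,Toshiba,One 320,320,16.0,51570,210889,87495,624837,46,188,19.6
CT-14,Toshiba,One 320,320,16.0,42147,91214,49348,237694,65,154,31.6
CT-15,Siemens,Definition AS+,64,3.84,90459,149228,341063,656315,112,371,37.7
CT-16,Siemens,Somatom Definition Edge,64,3.84,37670,187811,79236,815433,63,365,16.7
CT-17,Siemens,Somatom Definition Flash,128,3.84,26020,136504,65053,627337,41,315,16.0
CT-18,GE,Lightspeed VCT,64,4.0,52435,113908,120144,266720,48,172,31.5
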