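subject,group,age_lo,age_hi,time_since_injury,baseline_arat,ais,dropout,post_only
R01,ST,61,65,2,53,C3,0,0
R02,ST,46,50,26,47,C6,0,0
R03,ST,46,50,14,19,C5-6,0,0
R04,ST,56,60,3,16,C3,0,0
R05,AAN,21,25,2,35,C7-8,1,0
R06,AAN,21,25,1,,,1,0
R07,AAN,61,65,12,41,C6-7,0,0
R08,AAN,36,40,23,11,C4,0,0
R09,AAN,46,50,2,45,C4,0,1
R10,AAN,51,55,8,45,C4,0,0
R11,ST,46,50,16,7,C4,0,0
R12,AAN,46,50,16,21,C4,0,0
R13,AAN,56,60,37,20,C3,0,0
R14,ST,26,30,4,18,C3-4,1,0
R15,AAN,66,70,2,3,C4,0,0
R16,ST,46,50,36,21,C4,0,0
R17,ST,51,55,26,6,C4-5,0,0
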