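subject,age,sex,stai_mis,vas_mis,stai_mos,vas_mos,stai_ses,vas_ses
BJY,32,M,34,2,48,4,58,10
KKH,25,M,25,2,60,6,67,8
NES,25,F,25,2,48,6,65,10
KSH,28,M,28,2,64,8,71,6
LJK,30,M,30,2,52,4,68,6
LSW,25,F,25,2,68,8,71,6
KHJ,24,F,24,2,72,8,72,10
SHL,31,M,31,2,53,6,71,10
KMH,25,F,25,2,71,6,69,6
JHR,33,F,33,2,40,4,60,6
JHM,26,F,26,2,57,6,67,8
JSH,26,M,26,2,54,6,74,8
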