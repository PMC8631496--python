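stimulus,activity,sign,significant,epsilon
glucose,Agg,activating,false,
glucose,ColI,activating,false,
glucose,ColII,activating,false,
glucose,MMP3,activating,false,
glucose,ADAMTS4,activating,false,
pH,Agg,inhibiting,true,0.37
pH,ColI,activating,false,
pH,ColII,inhibiting,true,0.63
pH,MMP3,activating,true,28.7
pH,ADAMTS4,activating,true,5.7
IL1B,Agg,inhibiting,true,0.45
IL1B,ColI,activating,false,
IL1B,ColII,inhibiting,false,
IL1B,MMP3,activating,true,10.8
IL1B,ADAMTS4,inhibiting,false,
TNFA,Agg,inhibiting,false,
TNFA,ColI,inhibiting,true,0.31
TNFA,ColII,inhibiting,true,0.06
TNFA,MMP3,activating,true,26.85
TNFA,ADAMTS4,activating,true,5.77
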