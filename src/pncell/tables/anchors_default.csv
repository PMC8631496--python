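stimulus,activity,concentration,normalized_response
glucose,Agg,0,0.0000
glucose,Agg,0.5,0.3802
glucose,Agg,0.8,0.6307
glucose,Agg,1,0.7604
glucose,Agg,2,0.9832
glucose,Agg,5,1.0000
glucose,ColI,0,0.0000
glucose,ColI,0.5,0.3802
glucose,ColI,0.8,0.6307
glucose,ColI,1,0.7604
glucose,ColI,2,0.9832
glucose,ColI,5,1.0000
glucose,ColII,0,0.0000
glucose,ColII,0.5,0.3802
glucose,ColII,0.8,0.6307
glucose,ColII,1,0.7604
glucose,ColII,2,0.9832
glucose,ColII,5,1.0000
glucose,MMP3,0,0.0000
glucose,MMP3,0.5,0.3802
glucose,MMP3,0.8,0.6307
glucose,MMP3,1,0.7604
glucose,MMP3,2,0.9832
glucose,MMP3,5,1.0000
glucose,ADAMTS4,0,0.0000
glucose,ADAMTS4,0.5,0.3802
glucose,ADAMTS4,0.8,0.6307
glucose,ADAMTS4,1,0.7604
glucose,ADAMTS4,2,0.9832
glucose,ADAMTS4,5,1.0000
glucose,IL1B_mRNA,0,0.0000
glucose,IL1B_mRNA,0.5,0.3802
glucose,IL1B_mRNA,0.8,0.6307
glucose,IL1B_mRNA,1,0.7604
glucose,IL1B_mRNA,2,0.9832
glucose,IL1B_mRNA,5,1.0000
glucose,TNFA_mRNA,0,0.0000
glucose,TNFA_mRNA,0.5,0.3802
glucose,TNFA_mRNA,0.8,0.6307
glucose,TNFA_mRNA,1,0.7604
glucose,TNFA_mRNA,2,0.9832
glucose,TNFA_mRNA,5,1.0000
pH,Agg,7.4,0.0000
pH,Agg,7.2,0.0000
pH,Agg,7.0,0.0005
pH,Agg,6.9,0.0040
pH,Agg,6.8,0.0290
pH,Agg,6.6,0.6530
pH,Agg,6.5,1.0000
pH,ColI,7.4,0.0000
pH,ColI,7.2,0.0638
pH,ColI,7.0,0.3027
pH,ColI,6.9,0.5101
pH,ColI,6.8,0.7175
pH,ColI,6.6,0.9564
pH,ColI,6.5,1.0000
pH,ColII,7.4,0.0000
pH,ColII,7.2,0.3270
pH,ColII,7.0,0.8039
pH,ColII,6.9,0.9194
pH,ColII,6.8,0.9699
pH,ColII,6.6,0.9972
pH,ColII,6.5,1.0000
pH,MMP3,7.4,0.0000
pH,MMP3,7.2,0.0261
pH,MMP3,7.0,0.1845
pH,MMP3,6.9,0.3864
pH,MMP3,6.8,0.6397
pH,MMP3,6.6,0.9518
pH,MMP3,6.5,1.0000
pH,ADAMTS4,7.4,0.0000
pH,ADAMTS4,7.2,0.0261
pH,ADAMTS4,7.0,0.1845
pH,ADAMTS4,6.9,0.3864
pH,ADAMTS4,6.8,0.6397
pH,ADAMTS4,6.6,0.9518
pH,ADAMTS4,6.5,1.0000
pH,IL1B_mRNA,7.4,0.0000
pH,IL1B_mRNA,7.2,0.0019
pH,IL1B_mRNA,7.0,0.0247
pH,IL1B_mRNA,6.9,0.0819
pH,IL1B_mRNA,6.8,0.2409
pH,IL1B_mRNA,6.6,0.8411
pH,IL1B_mRNA,6.5,1.0000
pH,TNFA_mRNA,7.4,0.0000
pH,TNFA_mRNA,7.2,0.0638
pH,TNFA_mRNA,7.0,0.3027
pH,TNFA_mRNA,6.9,0.5101
pH,TNFA_mRNA,6.8,0.7175
pH,TNFA_mRNA,6.6,0.9564
pH,TNFA_mRNA,6.5,1.0000
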