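stimulus,activity,sign,significant,epsilon
glucose,IL1B_mRNA,activating,false,
glucose,TNFA_mRNA,activating,false,
pH,IL1B_mRNA,activating,true,81
pH,TNFA_mRNA,activating,false,
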