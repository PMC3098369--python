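linkage,type,phi_mean,phi_sd,psi_mean,psi_sd
U2-N1,beta1-3,-73,2,108,8
N3-U2,beta1-4,-73,0,-118,1
U4-N3,beta1-3,-73,0,107,0
N5-U4,beta1-4,-73,0,-116,0
U6-N5,beta1-3,-72,0,109,0
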