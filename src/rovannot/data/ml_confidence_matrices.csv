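conf_threshold,expert_label,predicted_label,count
0.5,Coral,Coral,54
0.5,Coral,NoCoral,15
0.5,NoCoral,Coral,13
0.5,NoCoral,NoCoral,50
0.7,Coral,Coral,52
0.7,Coral,NoCoral,17
0.7,NoCoral,Coral,5
0.7,NoCoral,NoCoral,58
0.9,Coral,Coral,28
0.9,Coral,NoCoral,41
0.9,NoCoral,Coral,1
0.9,NoCoral,NoCoral,62
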