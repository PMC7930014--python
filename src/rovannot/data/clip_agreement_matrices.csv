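agreement_threshold,expert_label,predicted_label,count
0.8,Coral,Coral,111
0.8,Coral,Other,467
0.8,Other,Coral,2
0.8,Other,Other,2014
0.6,Coral,Coral,315
0.6,Coral,Other,263
0.6,Other,Coral,22
0.6,Other,Other,1994
0.4,Coral,Coral,475
0.4,Coral,Other,103
0.4,Other,Coral,84
0.4,Other,Other,1932
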