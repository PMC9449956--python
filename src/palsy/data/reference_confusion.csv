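class,N,L_MI,R_MI,R_MO,R_S
N,40,0,0,0,0
L_MI,10,25,0,0,0
R_MI,0,0,10,0,0
R_MO,5,0,0,35,0
R_S,0,0,0,0,10
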