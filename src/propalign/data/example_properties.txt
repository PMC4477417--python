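Two-property demonstration set: hydrophobicity (weight 0.6) and size (weight 0.4)
A,R,N,D,C,Q,E,G,H,I,L,K,M,F,P,S,T,W,Y,V
#PROPERTY Hydrophobicity
0.25,-1.76,-0.6,-0.7,0.1,-0.7,-0.6,0.2,-0.4,0.7,0.5,-1.1,0.3,0.6,-0.1,-0.3,-0.2,0.4,0.1,0.5
W:0.6
#PROPERTY Size
28,105,59,40,45,81,62,0,79,94,94,100,94,112,42,23,51,146,117,72
W:0.4
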