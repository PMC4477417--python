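Default four-property set; implementer-sourced literature scales (Kyte-Doolittle hydropathy; Zamyatnin residue volume, A^3; coil conformational parameter; thiol indicator). Weights are the 30-40% identity preset.
A,R,N,D,C,Q,E,G,H,I,L,K,M,F,P,S,T,W,Y,V
#PROPERTY Hydrophobicity
1.8,-4.5,-3.5,-3.5,2.5,-3.5,-3.5,-0.4,-3.2,4.5,3.8,-3.9,1.9,2.8,-1.6,-0.8,-0.7,-0.9,-1.3,4.2
W:0.25
#PROPERTY Size
88.6,173.4,114.1,111.1,108.5,143.8,138.4,60.1,153.2,166.7,166.7,168.6,162.9,189.9,112.7,89.0,116.1,227.8,193.6,140.0
W:0.2
#PROPERTY Coil propensity
0.82,0.90,1.17,1.20,0.95,0.95,0.76,1.25,1.07,0.89,0.88,0.90,0.81,0.80,1.54,1.13,1.15,0.94,1.11,0.77
W:0.15
#PROPERTY Thiol group
0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
W:0.4
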