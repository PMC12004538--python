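t1,t2,delta_e_het,A,C,G,T,U
10,41,6.5,5.0,4.4,3.4,5.3,5.4
11,12,-4.4,-3.5,-1.1,-0.3,-2.9,-3.0
13,42,2.0,1.5,-1.0,-0.1,2.1,2.4
31,32,-4.0,-2.4,-1.9,-1.4,-2.8,-3.3
33,34,0.6,0.6,0.4,0.1,-0.8,-0.7
35,36,8.6,5.6,5.0,2.9,7.3,6.6
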