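sample_id,type,Ce,Dy,Er,Eu,Gd,Ho,La,Lu,Nd,Pr,Sm,Tb,Tm,Y,Yb
serbia_fly,fly,107,8.8,5.3,1.9,8.7,1.5,53,0.6,50,9.7,8.7,1.5,0.7,39,4.0
serbia_bottom,bottom,69,4.7,3.3,1.1,5.2,0.8,31,0.3,29,5.3,4.9,0.8,0.4,21,2.3
EU,fly,99,7.0,4.4,1.9,9.3,1.2,45,0.6,56,11,8.6,1.6,0.5,33,3.9
UK,fly,122,8.5,4.6,2.3,9.6,1.8,60,0.6,53,14,11,1.5,0.7,47,4.3
USA,fly,139,11,6.4,3.1,13,2.3,67,0.9,61,16,13,1.9,0.9,64,5.7
China,fly,177,11,6.5,2.5,14,2.2,84,0.9,75,19,14,2.0,0.9,57,5.9
SA,fly,167,10,5.6,2.5,12,1.9,87,0.7,66,18,13,1.7,0.7,58,4.2
India,fly,137,10,4.6,2.1,10,1.7,57,0.7,46,13,13,1.5,0.6,36,4.6
World,fly,157,11,6.9,2.6,14,2.1,73,0.8,71,17,13,2.0,0.9,59,5.8
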