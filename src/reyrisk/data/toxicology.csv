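element,tr,rfd,csf,source
Ce,1,0.02,3.2e-12,"Tr: REY toxicity-response literature; RfD/CSF: common REY values"
La,1,0.02,3.2e-12,"as Ce"
Y,2,0.02,3.2e-12,"as Ce"
Nd,2,0.02,3.2e-12,"as Ce"
Pr,5,0.02,3.2e-12,"as Ce"
Sm,5,0.02,3.2e-12,"as Ce"
Yb,5,0.02,3.2e-12,"as Ce"
Dy,5,0.02,3.2e-12,"as Ce"
Er,5,0.02,3.2e-12,"as Ce"
Gd,5,0.02,3.2e-12,"as Ce"
Ho,10,0.02,3.2e-12,"as Ce"
Tb,10,0.02,3.2e-12,"as Ce"
Tm,10,0.02,3.2e-12,"as Ce"
Eu,10,0.02,3.2e-12,"as Ce"
Lu,20,0.02,3.2e-12,"as Ce"
Hg,40,3.0e-4,,"Hakanson (1980); RfD Hg(II) worst case, USEPA IRIS"
Cd,30,1.0e-3,6.1,"Hakanson (1980); USEPA IRIS/RSL, oral CSF as used in soil HRA"
As,10,3.0e-4,1.5,"Hakanson (1980); inorganic As worst case, USEPA IRIS"
Cu,5,4.0e-2,,"Hakanson (1980); USEPA RSL"
Ni,5,2.0e-2,0.91,"Hakanson (1980); USEPA RSL, oral CSF as used in soil HRA"
Co,5,3.0e-4,9.8,"Hakanson (1980); USEPA RSL, oral CSF as used in soil HRA"
Pb,5,3.5e-3,8.5e-3,"Hakanson (1980); USEPA IEUBK-derived RfD, oral CSF"
Cr,2,3.0e-3,0.5,"Hakanson (1980); Cr(VI) worst case, USEPA IRIS"
Mn,1,1.4e-1,,"Hakanson (1980); USEPA IRIS dietary RfD"
Zn,1,3.0e-1,,"Hakanson (1980); USEPA IRIS"
Ba,,2.0e-1,,"USEPA IRIS; no Hakanson Tr assigned"
V,,5.0e-3,,"USEPA RSL; no Hakanson Tr assigned"
Mo,,5.0e-3,,"USEPA IRIS; no Hakanson Tr assigned"
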