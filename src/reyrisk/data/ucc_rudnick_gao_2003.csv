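element,value,unit,source
La,31,mg/kg,"Rudnick & Gao (2003), Treatise on Geochemistry vol. 3, upper continental crust"
Ce,63,mg/kg,"Rudnick & Gao (2003)"
Pr,7.1,mg/kg,"Rudnick & Gao (2003)"
Nd,27,mg/kg,"Rudnick & Gao (2003)"
Sm,4.7,mg/kg,"Rudnick & Gao (2003)"
Eu,1.0,mg/kg,"Rudnick & Gao (2003)"
Gd,4.0,mg/kg,"Rudnick & Gao (2003)"
Tb,0.7,mg/kg,"Rudnick & Gao (2003)"
Dy,3.9,mg/kg,"Rudnick & Gao (2003)"
Ho,0.83,mg/kg,"Rudnick & Gao (2003)"
Er,2.3,mg/kg,"Rudnick & Gao (2003)"
Tm,0.30,mg/kg,"Rudnick & Gao (2003)"
Yb,1.96,mg/kg,"Rudnick & Gao (2003)"
Lu,0.31,mg/kg,"Rudnick & Gao (2003)"
Y,21,mg/kg,"Rudnick & Gao (2003)"
As,4.8,mg/kg,"Rudnick & Gao (2003)"
Cr,92,mg/kg,"Rudnick & Gao (2003)"
V,97,mg/kg,"Rudnick & Gao (2003)"
Pb,17,mg/kg,"Rudnick & Gao (2003)"
Ni,47,mg/kg,"Rudnick & Gao (2003)"
Mn,775,mg/kg,"Rudnick & Gao (2003), from MnO 0.10 wt%"
Ba,628,mg/kg,"Rudnick & Gao (2003)"
Cd,0.09,mg/kg,"Rudnick & Gao (2003)"
Cu,28,mg/kg,"Rudnick & Gao (2003)"
Mo,1.1,mg/kg,"Rudnick & Gao (2003)"
Co,17.3,mg/kg,"Rudnick & Gao (2003)"
Hg,0.05,mg/kg,"Rudnick & Gao (2003)"
Zn,67,mg/kg,"Rudnick & Gao (2003)"
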