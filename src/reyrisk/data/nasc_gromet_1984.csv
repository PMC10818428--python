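element,value,unit,source
La,31.1,mg/kg,"Gromet et al. (1984), North American Shale Composite"
Ce,66.7,mg/kg,"Gromet et al. (1984)"
Pr,7.9,mg/kg,"companion interpolation to Gromet et al. (1984) NASC"
Nd,27.4,mg/kg,"Gromet et al. (1984)"
Sm,5.59,mg/kg,"Gromet et al. (1984)"
Eu,1.18,mg/kg,"Gromet et al. (1984)"
Gd,4.9,mg/kg,"companion interpolation to Gromet et al. (1984) NASC"
Tb,0.85,mg/kg,"Gromet et al. (1984)"
Dy,5.54,mg/kg,"companion interpolation to Gromet et al. (1984) NASC"
Ho,1.04,mg/kg,"companion interpolation to Gromet et al. (1984) NASC"
Er,3.4,mg/kg,"Gromet et al. (1984)"
Tm,0.50,mg/kg,"companion interpolation to Gromet et al. (1984) NASC"
Yb,3.06,mg/kg,"Gromet et al. (1984)"
Lu,0.456,mg/kg,"Gromet et al. (1984)"
Y,27,mg/kg,"Gromet et al. (1984)"
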