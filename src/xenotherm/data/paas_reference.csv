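element,ppm
La,38.2
Ce,79.6
Pr,8.83
Nd,33.9
Sm,5.55
Eu,1.08
Gd,4.66
Tb,0.774
Dy,4.68
Ho,0.991
Er,2.85
Tm,0.405
Yb,2.82
Lu,0.433
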