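ligand,receptor,family,mode
VEGFA,KDR,VEGF,secreted
VEGFA,FLT1,VEGF,secreted
VEGFA,NRP1,VEGF,secreted
VEGFA,NRP2,VEGF,secreted
VEGFB,FLT1,VEGF,secreted
VEGFC,FLT4,VEGF,secreted
TGFB1,TGFBR1,TGFB,secreted
TGFB1,TGFBR2,TGFB,secreted
TGFB2,TGFBR2,TGFB,secreted
TGFB3,TGFBR2,TGFB,secreted
BMP2,BMPR1A,BMP,secreted
BMP4,BMPR1A,BMP,secreted
BMP7,BMPR2,BMP,secreted
PDGFA,PDGFRA,PDGF,secreted
PDGFB,PDGFRB,PDGF,secreted
PDGFC,PDGFRA,PDGF,secreted
FGF1,FGFR1,FGF,secreted
FGF2,FGFR1,FGF,secreted
FGF7,FGFR2,FGF,secreted
FGF10,FGFR2,FGF,secreted
EGF,EGFR,EGF,secreted
TGFA,EGFR,EGF,secreted
HBEGF,EGFR,EGF,secreted
IGF1,IGF1R,IGF,secreted
IGF2,IGF1R,IGF,secreted
HGF,MET,HGF,secreted
IL6,IL6R,Interleukin,secreted
IL1B,IL1R1,Interleukin,secreted
IL10,IL10RA,Interleukin,secreted
IL15,IL15RA,Interleukin,secreted
TNF,TNFRSF1A,TNF,secreted
TNF,TNFRSF1B,TNF,secreted
CCL2,CCR2,Chemokine,secreted
CCL5,CCR5,Chemokine,secreted
CXCL12,CXCR4,Chemokine,secreted
CXCL8,CXCR2,Chemokine,secreted
CX3CL1,CX3CR1,Chemokine,secreted
DLL1,NOTCH1,Notch,contact
DLL4,NOTCH1,Notch,contact
JAG1,NOTCH2,Notch,contact
WNT3A,FZD1,Wnt,secreted
WNT5A,FZD2,Wnt,secreted
ANGPT1,TEK,Angiopoietin,secreted
ANGPT2,TEK,Angiopoietin,secreted
EFNA1,EPHA2,Ephrin,contact
EFNB2,EPHB4,Ephrin,contact
NGF,NTRK1,Neurotrophin,secreted
BDNF,NTRK2,Neurotrophin,secreted
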