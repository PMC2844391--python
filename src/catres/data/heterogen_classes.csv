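code,class
FE2,catalytic
MN,catalytic
CU1,catalytic
MG,catalytic
ZN3,catalytic
ZN,catalytic
HEM,catalytic
HEG,catalytic
HEC,catalytic
SRM,catalytic
MPD,catalytic
MRD,catalytic
FOK,catalytic
PLP,catalytic
P5P,catalytic
PHS,catalytic
OWQ,catalytic
NO3,catalytic
FS4,catalytic
SF4,catalytic
PVL,catalytic
PYR,catalytic
SEG,catalytic
DHZ,catalytic
FMT,catalytic
HAD,catalytic
CIT,catalytic
ACN,catalytic
PAC,catalytic
ACT,catalytic
2PE,catalytic
CNA,catalytic
U5P,catalytic
IKT,catalytic
PGC,catalytic
PGH,catalytic
IMU,catalytic
F6P,catalytic
IMP,catalytic
EEB,catalytic
GLP,catalytic
FBP,catalytic
UD1,catalytic
FCN,catalytic
AZA,catalytic
CRB,catalytic
DHS,catalytic
BME,catalytic
ATP,catalytic
ADP,catalytic
GSH,catalytic
FAD,catalytic
FMN,catalytic
SAM,catalytic
AMP,catalytic
NAD,catalytic
GDP,catalytic
GTP,catalytic
GMP,catalytic
MHF,catalytic
NDP,catalytic
NAG,catalytic
NRI,catalytic
K,non_catalytic
NA,non_catalytic
NI,non_catalytic
FE,non_catalytic
CA,non_catalytic
CL,non_catalytic
SAC,non_catalytic
FCY,non_catalytic
PCA,non_catalytic
MES,non_catalytic
MAN,non_catalytic
PO4,uncertain
PI,uncertain
IPS,uncertain
POP,uncertain
SO4,uncertain
SUL,uncertain
GOL,uncertain
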