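# Protein-coding genes of the male-specific region of chromosome Y
# (human symbols; override with --msy-list / msy_genes= for other builds).
SRY
RPS4Y1
ZFY
TBL1Y
AMELY
TSPY1
TSPY2
USP9Y
DDX3Y
UTY
TMSB4Y
VCY
VCY1B
NLGN4Y
CDY2A
CDY2B
HSFY1
HSFY2
KDM5D
EIF1AY
RPS4Y2
RBMY1A1
RBMY1B
RBMY1D
RBMY1E
RBMY1F
RBMY1J
PRY
PRY2
BPY2
BPY2B
BPY2C
DAZ1
DAZ2
DAZ3
DAZ4
CDY1
CDY1B
PCDH11Y
TGIF2LY
PRKY
XKRY
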