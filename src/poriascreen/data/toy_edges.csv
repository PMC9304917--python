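source,target,kind,score
AGTR1,MMP9,target-target,0.99
AGTR1,EDNRA,target-target,0.97
AGTR1,EDNRB,target-target,0.96
AGTR1,NR3C1,target-target,0.95
AGTR1,MAPK3,target-target,0.94
AGTR1,AVPR1A,target-target,0.93
AGTR1,CCKBR,target-target,0.92
MMP9,MAPK3,target-target,0.91
EDNRA,EDNRB,target-target,0.95
EDNRA,EDNRB,target-target,0.95
NR3C1,NR3C1,target-target,0.99
AGTR1,ADRB2,target-target,0.90
MMP9,PTGS2,target-target,0.85
pachymic acid,AGTR1,component-target,
pachymic acid,MMP9,component-target,
pachymic acid,NR3C1,component-target,
pachymic acid,MAPK3,component-target,
pachymic acid,EDNRA,component-target,
poricoic acid A,AGTR1,component-target,
poricoic acid A,EDNRB,component-target,
dehydrotrametenolic acid,MAPK3,component-target,
AGTR1,calcium signaling pathway,target-pathway,
MMP9,cancer pathway,target-pathway,
MAPK3,cGMP-PKG signaling pathway,target-pathway,
EDNRA,calcium signaling pathway,target-pathway,
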