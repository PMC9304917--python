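component,OB,DL
pachymic acid,33.6,0.81
dehydrotrametenolic acid,38.0,0.78
poricoic acid A,30.0,0.18
ergosterol peroxide,25.0,0.50
polysaccharide PC-1,40.0,0.10
trametenolic acid,29.9,0.80
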