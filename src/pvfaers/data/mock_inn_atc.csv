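inn,atc
dupilumab,A16AX
dupilumab,D11AH
dupilumab,R01
dupilumab,R03DX
ciclosporin,L04AD
ciclosporin,S01XA
ranibizumab,S01LA
aflibercept,L01XX
aflibercept,S01LA
bimatoprost,D11AX
bimatoprost,S01EE
fingolimod,L04AE
insulin glargine,A10AE
insulin lispro,A10A
insulin lispro,A10AB
insulin lispro,A10AC
insulin lispro,A10AD
botulinum toxin type a,A01AD
botulinum toxin type a,D11AA
botulinum toxin type a,D11AX
botulinum toxin type a,G04BD
botulinum toxin type a,M03AX
botulinum toxin type a,N02CX
cenegermin,S01XA
latanoprost,S01EE
lifitegrast,S01XA
bevacizumab,L01FG
bevacizumab,S01LA
docetaxel,L01CD
brolucizumab,S01LA
brimonidine,D11AX
brimonidine,S01EA
brimonidine,S01GA
sildenafil,C02KX
sildenafil,G04BE
insulin human,A10A
insulin human,A10AB
insulin human,A10AC
insulin human,A10AD
insulin human,A10AE
insulin human,A10AF
topiramate,N02CX
topiramate,N03AX
pentosan polysulfate,B01AB
pentosan polysulfate,C05BA
pentosan polysulfate,G04BX
prednisolone,A01AC
prednisolone,A07EA
prednisolone,C05AA
prednisolone,D07AA
prednisolone,H02AB
prednisolone,M02AX
prednisolone,R01AD
prednisolone,S01BA
prednisolone,S02BA
prednisolone,S03BA
tadalafil,C02KX
tadalafil,G04BE
tadalafil,G04CX
macrogol 400,A06AD
macrogol 400,S01XA
dorzolamide; timolol,S01ED
triamcinolone,A01AC
triamcinolone,C05AA
triamcinolone,D07AB
triamcinolone,H02AB
triamcinolone,R01AD
triamcinolone,R03BA
triamcinolone,S01BA
moxifloxacin,D06AX
moxifloxacin,J01MA
moxifloxacin,S01AE
moxifloxacin,S03AA
belantamab mafodotin,L01FX
amiodarone,C01BD
faricimab,S01LA
travoprost,S01EE
naphazoline; pheniramine,S01GA
mitomycin,L01DC
mitomycin,S01XA
netarsudil,S01EX
ivermectin,D11AX
ivermectin,P02CF
amantadine,N04BB
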