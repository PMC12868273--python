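verbatim,inn
dupilumab,dupilumab
dupixent,dupilumab
ciclosporin,ciclosporin
cyclosporine,ciclosporin
restasis,ciclosporin
ranibizumab,ranibizumab
lucentis,ranibizumab
aflibercept,aflibercept
eylea,aflibercept
bimatoprost,bimatoprost
lumigan,bimatoprost
fingolimod,fingolimod
gilenya,fingolimod
insulin glargine,insulin glargine
lantus,insulin glargine
insulin lispro,insulin lispro
humalog,insulin lispro
botulinum toxin type a,botulinum toxin type a
botox,botulinum toxin type a
cenegermin,cenegermin
oxervate,cenegermin
latanoprost,latanoprost
xalatan,latanoprost
lifitegrast,lifitegrast
xiidra,lifitegrast
bevacizumab,bevacizumab
avastin,bevacizumab
docetaxel,docetaxel
taxotere,docetaxel
brolucizumab,brolucizumab
beovu,brolucizumab
brimonidine,brimonidine
alphagan,brimonidine
sildenafil,sildenafil
viagra,sildenafil
insulin human,insulin human
topiramate,topiramate
topamax,topiramate
pentosan polysulfate,pentosan polysulfate
elmiron,pentosan polysulfate
prednisolone,prednisolone
tadalafil,tadalafil
cialis,tadalafil
macrogol 400,macrogol 400
dorzolamide; timolol,dorzolamide; timolol
cosopt,dorzolamide; timolol
triamcinolone,triamcinolone
moxifloxacin,moxifloxacin
vigamox,moxifloxacin
belantamab mafodotin,belantamab mafodotin
blenrep,belantamab mafodotin
amiodarone,amiodarone
cordarone,amiodarone
faricimab,faricimab
vabysmo,faricimab
travoprost,travoprost
travatan,travoprost
naphazoline; pheniramine,naphazoline; pheniramine
mitomycin,mitomycin
netarsudil,netarsudil
ivermectin,ivermectin
amantadine,amantadine
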