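drug,n_cases,tto_median,tto_q1,tto_q3,alpha,alpha_lo,alpha_hi,beta,beta_lo,beta_hi,reported_type
dupilumab,4862,29.00,0.00,150.00,156.34,148.32,164.81,0.68,0.66,0.69,early
fingolimod,3910,37.50,0.00,199.00,201.44,188.65,215.10,0.59,0.57,0.60,early
aflibercept,3215,63.00,1.00,435.00,280.61,261.22,301.43,0.58,0.56,0.60,early
botulinum toxin type a,3154,1.00,0.00,6.00,14.17,12.81,15.67,0.49,0.47,0.50,early
ranibizumab,2892,67.00,2.00,273.00,200.10,187.00,214.11,0.63,0.61,0.65,early
docetaxel,2540,63.00,18.50,265.00,152.58,144.17,161.47,0.76,0.73,0.78,early
ciclosporin,1857,0.00,0.00,16.00,69.56,59.19,81.74,0.44,0.42,0.46,early
bevacizumab,1617,7.00,0.00,107.00,90.57,80.58,101.79,0.52,0.50,0.54,early
cenegermin,1513,4.00,1.00,22.00,28.42,25.17,32.10,0.51,0.49,0.53,early
bimatoprost,1408,1.00,0.00,30.00,38.84,33.30,45.29,0.45,0.43,0.47,early
brolucizumab,1302,35.00,8.00,86.00,78.77,73.17,84.80,0.85,0.81,0.89,early
latanoprost,1203,61.00,0.00,731.00,559.18,493.57,633.51,0.57,0.54,0.60,early
lifitegrast,873,0.00,0.00,4.00,29.05,23.30,36.22,0.52,0.49,0.57,early
naphazoline; pheniramine,824,0.00,0.00,0.00,38.40,23.23,63.48,0.35,0.31,0.39,early
topiramate,801,9.00,3.00,30.00,53.35,44.71,63.66,0.46,0.44,0.48,early
tadalafil,772,7.00,0.00,161.00,135.16,111.33,164.09,0.46,0.43,0.49,early
sildenafil,764,30.00,0.00,609.50,452.60,383.74,533.82,0.55,0.51,0.59,early
insulin glargine,757,181.00,2.00,762.00,560.80,490.52,641.16,0.63,0.59,0.67,early
moxifloxacin,752,0.00,0.00,4.00,16.34,13.02,20.50,0.48,0.45,0.52,early
insulin lispro,626,366.00,3.00,1795.00,1215.49,1054.52,1401.03,0.65,0.60,0.70,early
brimonidine,597,0.00,0.00,5.00,76.74,55.70,105.71,0.41,0.37,0.45,early
faricimab,560,50.00,1.00,142.50,118.86,105.73,133.63,0.84,0.78,0.91,early
insulin human,532,1445.50,17.00,4017.00,2763.25,2439.08,3130.51,0.79,0.73,0.86,early
belantamab mafodotin,414,35.00,19.00,59.00,62.78,56.01,70.38,0.93,0.87,1.00,random
triamcinolone,372,1.00,0.00,6.00,30.72,21.42,44.06,0.38,0.35,0.42,early
prednisolone,367,2.00,0.00,14.00,47.75,33.85,67.36,0.41,0.37,0.45,early
pentosan polysulfate,359,269.00,0.00,3344.00,3313.91,2883.14,3809.03,1.03,0.91,1.16,random
macrogol 400,265,0.00,0.00,1.00,6.72,4.36,10.37,0.56,0.48,0.64,early
travoprost,240,1.00,0.00,54.00,71.06,48.80,103.48,0.45,0.40,0.50,early
dorzolamide; timolol,238,1.00,0.00,70.00,169.97,111.47,259.18,0.43,0.38,0.49,early
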