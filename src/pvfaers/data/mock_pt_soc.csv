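pt,soc
Vision blurred,Eye disorders
Visual impairment,Eye disorders
Cataract,Eye disorders
Eye pain,Eye disorders
Eye irritation,Eye disorders
Ocular hyperaemia,Eye disorders
Dry eye,Eye disorders
Blindness,Eye disorders
Eye swelling,Eye disorders
Visual acuity reduced,Eye disorders
Eye disorder,Eye disorders
Eye pruritus,Eye disorders
Lacrimation increased,Eye disorders
Diplopia,Eye disorders
Glaucoma,Eye disorders
Photophobia,Eye disorders
Conjunctivitis,Eye disorders
Blindness unilateral,Eye disorders
Eye haemorrhage,Eye disorders
Uveitis,Eye disorders
Mydriasis,Eye disorders
Madarosis,Eye disorders
Eyelid oedema,Eye disorders
Macular degeneration,Eye disorders
Eye infection,Eye disorders
Eyelid ptosis,Eye disorders
Ocular discomfort,Eye disorders
Eye discharge,Eye disorders
Vitreous floaters,Eye disorders
Pigmentary maculopathy,Eye disorders
Keratopathy,Eye disorders
Retinal pigmentation,Eye disorders
Corneal epithelial microcysts,Eye disorders
Punctate keratitis,Eye disorders
Corneal oedema,Eye disorders
Nausea,Gastrointestinal disorders
Vomiting,Gastrointestinal disorders
Diarrhoea,Gastrointestinal disorders
Headache,Nervous system disorders
Dizziness,Nervous system disorders
Rash,Skin and subcutaneous tissue disorders
Pruritus,Skin and subcutaneous tissue disorders
Alopecia,Skin and subcutaneous tissue disorders
Fatigue,General disorders and administration site conditions
Pyrexia,General disorders and administration site conditions
Drug ineffective,General disorders and administration site conditions
Injection site pain,General disorders and administration site conditions
Arthralgia,Musculoskeletal and connective tissue disorders
Dyspnoea,"Respiratory, thoracic and mediastinal disorders"
Cough,"Respiratory, thoracic and mediastinal disorders"
Insomnia,Psychiatric disorders
Anxiety,Psychiatric disorders
Seasonal allergy,Immune system disorders
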