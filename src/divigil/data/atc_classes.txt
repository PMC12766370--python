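# ATC anatomical main group (level 1) per standardized ingredient.
# Hand-curated subset of the WHO ATC index covering the ingredients in the
# bundled drug catalog. ingredient$class_code$class_label
dapagliflozin$A$Alimentary tract and metabolism
famotidine$A$Alimentary tract and metabolism
mannitol$B$Blood and blood forming organs
tolvaptan$C$Cardiovascular system
norepinephrine$C$Cardiovascular system
perindopril$C$Cardiovascular system
telmisartan$C$Cardiovascular system
hydrocortisone$H$Systemic hormonal preparations
somatropin$H$Systemic hormonal preparations
dexamethasone$H$Systemic hormonal preparations
octreotide$H$Systemic hormonal preparations
lanreotide$H$Systemic hormonal preparations
pegvisomant$H$Systemic hormonal preparations
amphotericin b$J$Anti-infectives for systemic use
tenofovir disoproxil$J$Anti-infectives for systemic use
piperacillin/tazobactam$J$Anti-infectives for systemic use
emtricitabine/tenofovir disoproxil$J$Anti-infectives for systemic use
voriconazole$J$Anti-infectives for systemic use
foscarnet$J$Anti-infectives for systemic use
dolutegravir$J$Anti-infectives for systemic use
efavirenz$J$Anti-infectives for systemic use
meropenem$J$Anti-infectives for systemic use
tigecycline$J$Anti-infectives for systemic use
demeclocycline$J$Anti-infectives for systemic use
doxycycline$J$Anti-infectives for systemic use
cidofovir$J$Anti-infectives for systemic use
temozolomide$L$Antineoplastic and immunomodulating agents
nivolumab$L$Antineoplastic and immunomodulating agents
pembrolizumab$L$Antineoplastic and immunomodulating agents
ipilimumab$L$Antineoplastic and immunomodulating agents
letrozole$L$Antineoplastic and immunomodulating agents
busulfan$L$Antineoplastic and immunomodulating agents
carboplatin$L$Antineoplastic and immunomodulating agents
cyclophosphamide$L$Antineoplastic and immunomodulating agents
pemetrexed$L$Antineoplastic and immunomodulating agents
cytarabine$L$Antineoplastic and immunomodulating agents
azacitidine$L$Antineoplastic and immunomodulating agents
etoposide$L$Antineoplastic and immunomodulating agents
ifosfamide$L$Antineoplastic and immunomodulating agents
vincristine$L$Antineoplastic and immunomodulating agents
methotrexate$L$Antineoplastic and immunomodulating agents
lithium$N$Nervous system
dexmedetomidine$N$Nervous system
quetiapine$N$Nervous system
levetiracetam$N$Nervous system
olanzapine$N$Nervous system
valproic acid$N$Nervous system
clozapine$N$Nervous system
risperidone$N$Nervous system
aripiprazole$N$Nervous system
sevoflurane$N$Nervous system
paroxetine$N$Nervous system
ketamine$N$Nervous system
phenytoin$N$Nervous system
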