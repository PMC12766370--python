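# Verbatim drug name -> standardized ingredient. Keys are pre-normalized
# (case-folded, whitespace-collapsed, surrounding punctuation stripped).
# Hand-curated stand-in for DrugBank/MeSH name standardization, covering the
# bundled catalog plus common salt, brand and combination spellings.
# verbatim$ingredient
dapagliflozin$dapagliflozin
dapagliflozin propanediol$dapagliflozin
farxiga$dapagliflozin
famotidine$famotidine
pepcid$famotidine
mannitol$mannitol
tolvaptan$tolvaptan
samsca$tolvaptan
norepinephrine$norepinephrine
norepinephrine bitartrate$norepinephrine
noradrenaline$norepinephrine
perindopril$perindopril
perindopril erbumine$perindopril
telmisartan$telmisartan
hydrocortisone$hydrocortisone
hydrocortisone sodium succinate$hydrocortisone
somatropin$somatropin
dexamethasone$dexamethasone
dexamethasone sodium phosphate$dexamethasone
octreotide$octreotide
octreotide acetate$octreotide
sandostatin$octreotide
lanreotide$lanreotide
lanreotide acetate$lanreotide
pegvisomant$pegvisomant
amphotericin b$amphotericin b
liposomal amphotericin b$amphotericin b
tenofovir disoproxil$tenofovir disoproxil
tenofovir disoproxil fumarate$tenofovir disoproxil
viread$tenofovir disoproxil
piperacillin/tazobactam$piperacillin/tazobactam
piperacillin and tazobactam$piperacillin/tazobactam
zosyn$piperacillin/tazobactam
emtricitabine/tenofovir disoproxil$emtricitabine/tenofovir disoproxil
emtricitabine and tenofovir disoproxil$emtricitabine/tenofovir disoproxil
truvada$emtricitabine/tenofovir disoproxil
voriconazole$voriconazole
vfend$voriconazole
foscarnet$foscarnet
foscarnet sodium$foscarnet
dolutegravir$dolutegravir
dolutegravir sodium$dolutegravir
efavirenz$efavirenz
meropenem$meropenem
tigecycline$tigecycline
tygacil$tigecycline
demeclocycline$demeclocycline
demeclocycline hydrochloride$demeclocycline
doxycycline$doxycycline
doxycycline hyclate$doxycycline
cidofovir$cidofovir
temozolomide$temozolomide
temodar$temozolomide
nivolumab$nivolumab
opdivo$nivolumab
pembrolizumab$pembrolizumab
keytruda$pembrolizumab
ipilimumab$ipilimumab
yervoy$ipilimumab
letrozole$letrozole
femara$letrozole
busulfan$busulfan
carboplatin$carboplatin
cyclophosphamide$cyclophosphamide
cytoxan$cyclophosphamide
pemetrexed$pemetrexed
pemetrexed disodium$pemetrexed
cytarabine$cytarabine
azacitidine$azacitidine
etoposide$etoposide
ifosfamide$ifosfamide
vincristine$vincristine
vincristine sulfate$vincristine
methotrexate$methotrexate
methotrexate sodium$methotrexate
lithium$lithium
lithium carbonate$lithium
lithium citrate$lithium
dexmedetomidine$dexmedetomidine
dexmedetomidine hcl$dexmedetomidine
dexmedetomidine hydrochloride$dexmedetomidine
precedex$dexmedetomidine
quetiapine$quetiapine
quetiapine fumarate$quetiapine
seroquel$quetiapine
levetiracetam$levetiracetam
keppra$levetiracetam
olanzapine$olanzapine
zyprexa$olanzapine
valproic acid$valproic acid
valproate sodium$valproic acid
divalproex sodium$valproic acid
clozapine$clozapine
clozaril$clozapine
risperidone$risperidone
risperdal$risperidone
aripiprazole$aripiprazole
abilify$aripiprazole
sevoflurane$sevoflurane
paroxetine$paroxetine
paroxetine hydrochloride$paroxetine
ketamine$ketamine
ketamine hydrochloride$ketamine
phenytoin$phenytoin
phenytoin sodium$phenytoin
dilantin$phenytoin
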