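# MedDRA preferred-term subset used by the synthetic generator and tests.
# Hand-curated stand-in for the licensed MedDRA dictionary (flat PT level only).
# pt_cod$pt_name
10012599$Diabetes insipidus
10028813$Nausea
10019211$Headache
10047700$Vomiting
10012735$Diarrhoea
10013573$Dizziness
10016256$Fatigue
10037844$Rash
10037660$Pyrexia
10017955$Drug ineffective
10036142$Polyuria
10021036$Hyponatraemia
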