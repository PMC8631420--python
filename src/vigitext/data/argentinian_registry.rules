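# Boolean rules deriving the registry's disjoint AE categories from the
# 12 canonical symptom classes (evaluated per report).
fever_pain = fever AND (pain OR headache)
fatigue_pain = fatigue AND (pain OR headache)
gastric = nausea_vomiting OR diarrhea
site_irritation = pruritus OR erythema OR swelling
only_fever = fever AND NOT (pain OR headache OR fatigue)
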