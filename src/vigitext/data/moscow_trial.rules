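# Frequency-sum rules collapsing the trial's AE vocabulary onto the
# package's symptom classes.  target = source term + source term + ...
fever = pyrexia + fever sensation + elevated body temperature
pain = myalgia + arthralgia + local reaction
fatigue = asthenia + malaise
nausea = nausea + dyspepsia
erythema = contact dermatitis
headache = headache
diarrhea = diarrhea
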