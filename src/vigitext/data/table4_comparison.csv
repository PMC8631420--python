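category,trial_count,trial_percent,telegram_count,telegram_percent
pain,67,6.70,177,25.65
headache,30,2.92,89,12.90
fatigue,31,3.01,141,20.43
fever,32,3.11,163,23.62
nausea,12,1.17,9,1.30
erythema,39,3.79,15,2.17
diarrhea,8,0.78,3,0.43
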