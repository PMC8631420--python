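category,registry_count,registry_percent,telegram_count,telegram_percent
fever_pain,8210,33.25,4142,54.70
fatigue_pain,9407,38.10,2998,39.67
gastric,1447,5.98,395,5.14
site_irritation,2306,9.34,558,7.31
only_fever,2065,8.34,697,9.53
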