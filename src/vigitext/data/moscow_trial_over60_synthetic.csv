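# SYNTHETIC fixture: the published trial reports only category totals for
# its over-60 safety cohort (n=1029); this split of each total across the
# trial's source vocabulary is constructed so the frequency-sum rules
# reproduce the published aggregated counts.
category,count,denominator
pyrexia,20,1029
fever sensation,8,1029
elevated body temperature,4,1029
myalgia,30,1029
arthralgia,17,1029
local reaction,20,1029
asthenia,19,1029
malaise,12,1029
nausea,8,1029
dyspepsia,4,1029
contact dermatitis,39,1029
headache,30,1029
diarrhea,8,1029
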