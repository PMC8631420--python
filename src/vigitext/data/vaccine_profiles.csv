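vaccine,source,platform,pain,headache,fatigue,fever,chills,nausea
AstraZeneca,EMA,vector,54.20,52.60,53.10,41.50,31.90,21.80
Johnson & Johnson,EMA,vector,48.60,38.90,38.20,14.00,5.00,14.20
Johnson & Johnson,CDC,vector,59.80,44.40,43.80,12.80,5.00,15.50
Pfizer,EMA,mRNA,80.00,50.00,60.00,30.00,30.00,5.00
Pfizer,CDC,mRNA,77.80,51.70,59.40,15.80,35.10,10.00
Sputnik V,Telegram,vector,46.57,24.80,33.54,47.43,23.02,3.00
Moderna,CDC,mRNA,90.10,62.80,67.60,17.40,48.30,21.30
Moderna,EMA,mRNA,92.00,64.70,70.00,15.50,45.40,23.00
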