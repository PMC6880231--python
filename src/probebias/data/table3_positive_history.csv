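participant,age,baseline_bias,current_drug,drug_history,n_substances,age_onset,age_problematic_use,frequency
001,46,30.3,Stimulants,Polysubstance,9,45,45,"Daily (1-2 grams, once per day)"
003,35,6.7,Stimulants,Polysubstance,7,31,31,"Daily (0.5 grams, once per day)"
004,46,32.1,Opioids,Polysubstance,12,14,17,"Daily (30-40 mL, 1-2 times per day)"
005,26,91.2,Alcohol,Alcohol,1,20,21,"Daily (750 mL, 2-3 times per day)"
006,64,98.9,Opioids,Polysubstance,11,20,22,"Daily (2 Straws, once daily)"
008,60,58.7,Opioids,Polysubstance,4,13,13,"Daily (1 Straw, 2 times daily)"
009,28,25.8,Opioids,Polysubstance,5,17,19,"Daily (1.5 straws, 6 times daily)"
012,28,0.7,Opioids,Polysubstance,5,18,25,"Daily (5 tablets, 5 times daily)"
014,61,397.7,Alcohol,Polysubstance,5,13,27,"Daily (3 tall cans, 2 times daily)"
018,54,27.9,Opioids,Polysubstance,5,34,34,"*Patient did not fill up"
019,57,3.8,Opioids,Polysubstance,3,40,40,"Daily (90 mL, once per day)"
020,45,10.1,Opioids,Polysubstance,4,23,23,"Daily (1 straw, 3 times daily)"
021,50,224.5,Alcohol,Alcohol & tobacco,2,15,50,"Daily (8 cans, once daily)"
030,48,1.3,Opioids,Polysubstance,3,16,16,"Daily (4 Straws, 4 times daily)"
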