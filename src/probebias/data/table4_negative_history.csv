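participant,age,baseline_bias,current_drug,drug_history,n_substances,age_onset,age_problematic_use,frequency
002,44,-22.4,Stimulants,Polysubstance,4,38,40,"Daily (Unknown quantity, 6 times daily)"
007,32,-30.5,Stimulants,Polysubstance,3,29,30,"Daily (0.3 grams, 5 times daily)"
010,59,-9.9,Cannabis,Polysubstance,5,59,59,"Daily (2 joints once per day)"
011,50,-30.9,Opioids,Polysubstance,3,24,24,"Daily (4 straws, 4 times per day)"
013,42,-20.9,Alcohol,Alcohol and tobacco,2,18,18,"Daily (3-4 bottles, 3 times per day)"
015,57,-7.7,Cannabis,Polysubstance,7,57,57,"Daily (1 joint, 20 times per day)"
016,47,-27.4,Opioids,Polysubstance,6,17,17,"Daily (1 joint, 6-7 times per day)"
017,63,-42.5,Opioids,Polysubstance,4,16,17,"Daily (0.5 straws, 3 times per day)"
022,43,-52.9,Opioids,Polysubstance,6,16,17,"Daily (2 straws, 2 times per day)"
023,54,-36.4,Opioids,Polysubstance,6,15,16,"Daily (3 straws, 10 times per day)"
024,46,-16.9,Opioids,Tobacco & heroin,2,17,21,"Daily (7 straws, 4 times per day)"
026,57,-77.1,Opioids,Tobacco & heroin,2,17,28,"Daily (1 straw, 2 times per day)"
027,31,-15.2,Stimulants,Polysubstance,9,17,25,"Daily (0.3 grams throughout the day)"
028,44,-33.3,Alcohol,Alcohol and tobacco,2,17,28,"Daily (750 mL, 16-18 times per day)"
029,39,-41.4,Alcohol,Polysubstance,3,14,30,"Daily (9-10 cans, 9 times per day)"
031,25,-38.4,Opioids,Polysubstance,8,20,20,"Daily (1 straw, 2 times per day)"
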