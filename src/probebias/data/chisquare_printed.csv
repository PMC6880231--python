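factor,statistic,df,p,reproducible
nationality,0.536,1,0.46,1
gender,0.871,1,0.35,1
substance,1.875,3,0.60,0
race,1.014,3,0.80,0
education,4.078,3,0.25,1
employment,1.598,2,0.45,1
housing,11.92,6,0.06,1
psychiatric_disorder,0.536,1,0.46,1
physical_disorder,1.916,1,0.38,0
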