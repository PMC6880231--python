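factor,level,positive_n,negative_n
substance,Alcohol,3,3
substance,Opioids,9,8
substance,Cannabis,0,2
substance,Stimulants,2,3
nationality,Singaporean,12,15
nationality,Others,2,1
gender,Male,13,13
gender,Female,1,3
race,Chinese,4,3
race,Malay,6,7
race,Indian,3,6
race,Others,1,1
education,Primary education,4,3
education,Secondary education,7,9
education,Junior college or polytechnic/technical studies,1,4
education,Undergraduate studies,2,0
employment,Unemployed,10,13
employment,Part-time employment,1,2
employment,Full-time employment,3,1
housing,Homeless,4,2
housing,1 room,4,4
housing,2 rooms,2,0
housing,3 rooms,1,2
housing,4 rooms,0,7
housing,5 rooms,2,0
housing,Others,1,1
psychiatric_disorder,Yes,2,1
psychiatric_disorder,No,12,15
physical_disorder,Yes,4,7
physical_disorder,No,10,9
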