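participant,drug,footnotes,baseline,post1,post2,post3,post4,post5,reason1,reason2,reason3,reason4,reason5,printed_change,printed_direction
001,Stimulants,,30.3,70.6,36.3,9.3,-23.6,13.3,none,none,none,none,none,17.0,decreased
002,Stimulants,a,-22.4,-23.4,-11.7,,,,none,none,dropout,dropout,dropout,10.7,increased
003,Stimulants,,6.7,-3.6,-28.9,-11.3,4.1,-7.3,none,none,none,none,none,14.0,decreased
004,Opioid,c,32.1,28.7,12.2,31.2,20.1,,none,none,none,none,holiday,12.0,decreased
005,Alcohol,c,91.2,-23.3,-37.4,-5.3,-33.2,,none,none,none,none,holiday,124.4,decreased
006,Opioid,c,98.9,33.4,14.5,-9.7,-31.5,,none,none,none,none,holiday,130.4,decreased
007,Stimulants,,-30.5,-13.5,-23.4,-27.7,-28.2,-7.6,none,none,none,none,none,22.9,increased
008,Opioids,a,58.7,85.1,,,,,none,dropout,dropout,dropout,dropout,26.4,increased
009,Opioids,a,25.8,13.5,,,,,none,dropout,dropout,dropout,dropout,12.3,decreased
010,Cannabis,,-9.9,-20.7,-54.6,-14.1,-22.9,-48.4,none,none,none,none,none,38.5,decreased
011,Opioids,,-30.9,2.4,-15.4,-7.4,14.2,7.3,none,none,none,none,none,38.2,increased
012,Opioids,a,0.7,34.8,-15.3,-52.4,,,none,none,none,dropout,dropout,53.1,decreased
013,Alcohol,d,-20.9,-12.3,,,-75.8,-48.6,none,technical,technical,none,none,27.7,decreased
014,Alcohol,a,397.7,44.2,45.3,-32.0,-11.7,,none,none,none,none,dropout,409.4,decreased
015,Cannabis,,-7.7,-40.5,8.6,-33.6,-31.8,-50.3,none,none,none,none,none,42.6,decreased
016,Opioids,a,-27.4,,,,,,dropout,dropout,dropout,dropout,dropout,,
017,Opioids,,-42.5,-64.8,63.4,8.9,-15.5,26.7,none,none,none,none,none,69.2,increased
018,Opioids,,27.9,-17.8,3.2,-22.6,-104.6,-9.2,none,none,none,none,none,37.1,decreased
019,Opioids,a,3.8,35.1,13.7,32.4,,,none,none,none,dropout,dropout,28.6,increased
020,Opioids,,10.1,9.4,105.2,54.1,-1.7,20.3,none,none,none,none,none,10.2,increased
021,Alcohol,,224.5,61.5,73.3,176.7,130.3,107.0,none,none,none,none,none,117.4,decreased
022,Opioids,,-52.9,10.9,5.6,39.1,36.5,76.6,none,none,none,none,none,129.6,increased
023,Opioids,,-36.4,18.0,45.0,74.8,35.9,41.3,none,none,none,none,none,77.7,increased
024,Opioids,a,-16.9,45.2,1.49,3.8,33.9,,none,none,none,none,dropout,50.8,increased
026,Opioids,a,-77.1,-82.5,,,,,none,dropout,dropout,dropout,dropout,5.4,decreased
027,Stimulants,,-15.2,-11.6,10.1,-27.0,-25.7,-1.6,none,none,none,none,none,13.6,increased
028,Alcohol,,-33.3,-29.4,-48.3,-10.9,-15.6,-11.6,none,none,none,none,none,21.8,increased
029,Alcohol,a,-41.4,-18.0,20.6,28.2,,,none,none,none,dropout,dropout,69.6,increased
030,Opioids,,1.3,38.6,7.9,11.5,13.0,-8.9,none,none,none,none,none,10.2,decreased
031,Opioids,a,-38.4,-282.7,-166.4,-190.1,,,none,none,none,dropout,dropout,151.6,decreased
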