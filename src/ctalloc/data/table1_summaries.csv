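group,range_days,n_units,variable,sum,mean,sd,min,max
Short,1-33,33,population,3613753,109507.7,54156,35193,297554
Short,1-33,33,female_pct,ND,52.0,1.1,50.0,54.746
Short,1-33,33,male_pct,ND,48.0,1.1,45.3,50.0
Short,1-33,33,over65,691161,20944.3,10463.4,5655,52967
Short,1-33,33,under14,526187,15945.1,8638.8,4648,45189
Short,1-33,33,diagnosed_with_ct,177941,5392.2,5474.1,1252,25340
Short,1-33,33,ct_scanners,101,3.1,2.0,2,13
Short,1-33,33,ct_procedures,501332,15191.9,21253.3,2011,97837
Short,1-33,33,procedures_per_patient,80.2,2.4,0.7,1.5,4.11
Short,1-33,33,patients_waiting,11293,342.2,ND,32,1169
Medium,34-98,65,population,8060044,124000.7,ND,24513,348190
Medium,34-98,65,female_pct,ND,52.7,1.2,49.9,55.0
Medium,34-98,65,male_pct,ND,47.3,1.2,45.0,50.1
Medium,34-98,65,over65,1630879,25090.4,15423.1,3992,75715
Medium,34-98,65,under14,1223938,18829.8,9952.3,4011,50032
Medium,34-98,65,diagnosed_with_ct,552536,8500.6,9276.6,171,43420
Medium,34-98,65,ct_scanners,306,4.7,3.9,2,23
Medium,34-98,65,ct_procedures,1754639,26994.4,37161.9,269,208486
Medium,34-98,65,procedures_per_patient,176.4,2.7,0.7,1.5,4.8
Medium,34-98,65,patients_waiting,102686,1579.8,1411.6,100.0,4269
Long,99-130,32,population,5068719,158397.5,ND,46291,470907
Long,99-130,32,female_pct,ND,52.4,1.0,50.4,55.0
Long,99-130,32,male_pct,ND,47.6,1.0,46.2,49.6
Long,99-130,32,over65,1010497,31578.0,19499.2,9676,96394
Long,99-130,32,under14,743630,23238.4,13175.7,6285,72801
Long,99-130,32,diagnosed_with_ct,389340,12166.9,9214.3,2022,37407
Long,99-130,32,ct_scanners,277,8.7,9.1,2,28
Long,99-130,32,ct_procedures,1184735,37023.0,32218.1,4049,129.82
Long,99-130,32,procedures_per_patient,88.9,2.8,0.6,1.7,3.9
Long,99-130,32,patients_waiting,39955,1248.6,1036.9,41,4914
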