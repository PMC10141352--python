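category,label,n_units,statistic,female_ratio,under14_share,over65_share,population,ct_procedures,ea_scanners,historical_scanners,waiting_days
A,underinvestment of CT,9,mean,0.53,0.15,0.21,145609,7596,4.89,3.67,69
A,underinvestment of CT,9,median,0.53,0.14,0.21,124992,6513,5.00,3.00,64
A,underinvestment of CT,9,min,0.52,0.11,0.17,78244,1505,4.00,2.00,48
A,underinvestment of CT,9,max,0.55,0.18,0.25,246348,15349,6.00,5.00,122
B,potential for further development of the equipment infrastructure,3,mean,0.51,0.15,0.19,91641,3681,3.50,2.50,6.96
B,potential for further development of the equipment infrastructure,3,median,0.51,0.15,0.19,91641,3681,3.50,2.50,6.96
B,potential for further development of the equipment infrastructure,3,min,0.50,0.14,0.16,35193,2237,3.00,2.00,5.00
B,potential for further development of the equipment infrastructure,3,max,0.52,0.16,0.21,148089,5124,4.00,3.00,8.92
C,potential for efficiency gains,35,mean,0.53,0.16,0.19,156436,11660,3.56,9.44,61.56
C,potential for efficiency gains,35,median,0.53,0.15,0.20,131296,8541,3.00,5.00,53.45
C,potential for efficiency gains,35,min,0.50,0.12,0.09,24513,171,0.00,2.00,47.89
C,potential for efficiency gains,35,max,0.55,0.26,0.24,483789,38896,10.00,28.00,129.12
D,overproduction of CT,5,mean,0.51,0.15,0.18,98247,3083,1.40,2.80,6.24
D,overproduction of CT,5,median,0.51,0.15,0.18,76256,2859,2.00,3.00,6.00
D,overproduction of CT,5,min,0.51,0.13,0.17,55790,1252,0.00,2.00,3.92
D,overproduction of CT,5,max,0.52,0.16,0.18,178191,6569,2.00,4.00,9.14
E,underconsumption of CT scans,10,mean,0.53,0.15,0.19,146319,6954,4.50,3.00,18.38
E,underconsumption of CT scans,10,median,0.52,0.15,0.19,129905,4278,4.00,3.00,12.74
E,underconsumption of CT scans,10,min,0.51,0.10,0.15,47028,1380,4.00,2.00,11.93
E,underconsumption of CT scans,10,max,0.55,0.19,0.25,308070,24076,6.00,4.00,40.23
F,overconsumption of CT scans,18,mean,0.52,0.15,0.19,222157,16481,3.00,8.44,29.86
F,overconsumption of CT scans,18,median,0.52,0.15,0.19,182758,9106,2.50,6.00,28.84
F,overconsumption of CT scans,18,min,0.51,0.12,0.14,64760,2661,0.00,2.00,12.74
F,overconsumption of CT scans,18,max,0.54,0.20,0.27,495350,43420,7.00,23.00,47.03
G,agreement,39,mean,0.52,0.15,0.19,137813,6190,2.79,2.77,25.64
G,agreement,39,median,0.52,0.15,0.19,136112,4931,3.00,2.00,26.11
G,agreement,39,min,0.50,0.12,0.13,30833,1324,1.00,2.00,10.00
G,agreement,39,max,0.55,0.19,0.29,300590,27348,6.00,6.00,46.95
unclassified,unclassified,11,mean,0.51,0.15,0.18,136670,4728,2.15,2.15,43.22
unclassified,unclassified,11,median,0.51,0.15,0.18,139946,3790,2.00,2.00,48.42
unclassified,unclassified,11,min,0.50,0.13,0.15,63014,1483,2.00,2.00,4.94
unclassified,unclassified,11,max,0.52,0.17,0.21,253142,13128,3.00,3.00,114.34
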