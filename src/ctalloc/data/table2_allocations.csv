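unit_code,unit_name,ea_scanners,historical_scanners
0202,dzierzoniowski,3,3
0206,jeleniogórski,1,2
0208,kłodzki,1,2
0211,lubiński,3,3
0219,świdnicki,2,2
0225,zgorzelecki,3,2
0261,City-Jelenia Góra,2,3
0262,City-Legnica,4,2
0264049,City-Wroclaw-Psie Pole District,4,ND
0264069,City-Wroclaw-Srodmiescie District,1,ND
0264059,City-Wroclaw-Old Town District,6,ND
0264039,City-Wroclaw-Krzyki District,4,ND
0264029,City-Wroclaw-Fabryczna District,4,ND
0264,City-Wroclaw,19,18
0461,City-Bydgoszcz,6,18
0462,City-Grudziądz,1,3
0463,City-Toruń,4,6
0464,City-Włocławek,3,3
0614,puławski,3,3
0661,City-Biała Podlaska,3,2
0662,City-Chełm,2,2
0663,City-Lublin,6,21
0664,City-Zamość,2,4
0804,nowosolski,2,2
0807,sulęciński,3,2
0808,świebodziński,2,3
0811,żarski,2,2
0861,City-Gorzów Wielkopolski,4,3
0862,City-Zielona Góra,4,3
1003,laski,3,2
1008,pabianicki,5,2
1016,tomaszowski,3,3
1017,wieluński,1,2
1019,zduńskowolski,2,2
1020,zgierski,3,5
1021,brzeziński,1,1
1061059,City-Lodz-Śródmieście District,2,8
1061069,City-Lodz-Widzew District,4,15
1061029,City-Lodz-Baluty District,6,10
1061039,City-Lodz-Gorna District,6,11
1061049,City-Lodz-Polesie District,5,9
1205,gorlicki,1,2
1207,limanowski,2,2
1211,nowotarski,2,4
1217,tatrzański,4,2
1261029,City-Krakow-Krowodrza District,6,8
1261039,City-Krakow-Nowa Huta District,6,6
1261049,City-Krakow-Podgorze District,7,4
1261059,City-Krakow-Srodmiescie District,4,14
1262,City-Nowy Sącz,2,2
1263,City-Tarnów,2,4
1405,grodziski,4,2
1407,kozienicki,0,2
1417,otwocki,2,5
1418,piaseczyński,5,4
1428,sochaczewski,3,2
1433,węgrowski,3,2
1462,City-Płock,1,3
1463,City-Radom,3,8
1464,City-Siedlce,1,3
1465078,City-Warsaw-Praga Południe District,3,11
1465168,City-Warsaw-Wilanów District,4,2
1465058,City-Warsaw-Mokotow District,5,15
1465158,City-Warsaw-Wesoła District,2,0
1465028,City-Warsaw-Bemowo District,4,0
1465198,City-Warsaw-Żoliborz District,3,5
1465098,City-Warsaw-Rembertów District,2,0
1465068,City-Warsaw-Ochota District,4,13
1465048,City-Warsaw-Bielany District,4,5
1465038,City-Warsaw-Białołeka District,2,0
1465128,City-Warsaw-Ursus District,2,1
1465088,City-Warsaw-Praga Północ District,2,5
1465138,City-Warsaw-Ursynów District,4,11
1465148,City-Warsaw-Wawer District,5,4
1465108,City-Warsaw-Śródmieście District,6,11
1465188,City-Warsaw-Wola District,3,4
1465178,City-Warsaw-Włochy District,3,1
1465118,City-Warsaw-Targówek District,5,2
1604,kluczborski,0,2
1802,brzozowski,2,4
1811,mielecki,3,2
1816,rzeszowski,2,2
1818,stalowowolski,2,2
1861,City-Krosno,2,2
1862,City-Przemyśl,3,2
1863,City-Rzeszów,3,12
2061,City-Białystok,7,11
2063,City-Suwałki,0,2
2202,chojnicki,1,2
2206,kościerski,2,2
2207,kwidzyński,2,2
2215,wejherowski,2,5
2261,City-Gdańsk,8,11
2262,City-Gdynia,6,3
2263,City-Słupsk,2,3
2401,będziński,4,2
2403,cieszyński,2,6
2405,gliwicki,2,3
2411,raciborski,4,2
2413,tarnogórski,5,2
2416,zawierciański,4,2
2461,City-Bielsko-Biała,3,6
2462,City-Bytom,5,6
2463,City-Chorzów,3,2
2464,City-Częstochowa,4,6
2465,City-Dąbrowa Górnicza,4,3
2466,City-Gliwice,4,5
2469,City-Katowice,6,18
2471,City-Piekary Śląskie,1,2
2473,City-Rybnik,2,2
2475,City-Sosnowiec,5,5
2477,City-Tychy,2,2
2478,City-Zabrze,5,4
2607,ostrowiecki,2,2
2610,skarżyski,2,2
2661,City-Kielce,3,9
2861,City-Elbląg,3,3
2862,City-Olsztyn,6,10
3017,ostrowski,3,2
3019,pilski,2,3
3020,pleszewski,2,2
3061,City-Kalisz,3,2
3062,City-Konin,3,3
3063,City-Leszno,2,3
3064049,City-Poznan-Nowe Miasto District,2,9
3064059,City-Poznan-Stare Miasto District,3,11
3064039,City-Poznan-Jezyce District,3,11
3064029,City-Poznan-Grunwald,1,6
3064069,City-Poznan-Wilda District,2,2
3261,City-Szczecin,4,4
3262,City-Świnoujście,10,11
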