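code,label,suitability
1,Continuous urban fabric,0.2
2,Discontinuous urban fabric,1
3,Industrial or commercial units,0.2
4,Road and rail networks and associated land,0.5
5,Port areas,0.8
6,Airports,0.2
7,Mineral extraction sites,0
8,Dump sites,0.2
9,Construction sites,0.3
10,Green urban areas,1
11,Sport and leisure facilities,1
12,Non-irrigated arable land,0
15,Vineyards,0.1
16,Fruit trees and berry plantations,0.3
18,Pastures,0.2
20,Complex cultivation patterns,0.1
21,"Land principally occupied by agriculture, with significant areas of natural vegetation",0.2
23,Broad-leaved forest,0.9
24,Coniferous forest,0.1
25,Mixed forest,0.8
26,Natural grasslands,0
27,Moors and heathland,0
29,Transitional woodland-shrub,0.6
30,"Beaches, dunes, sands",0
31,Bare rocks,0.1
32,Sparsely vegetated areas,0
34,Glaciers and perpetual snow,0
35,Inland marshes,0
36,Peat bogs,0
37,Salt marshes,0
39,Intertidal flats,0
40,Water courses,0
41,Water bodies,0
42,Coastal lagoons,0
43,Estuaries,0
44,Sea and ocean,0
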