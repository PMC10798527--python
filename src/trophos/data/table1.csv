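id,name,category,tl,biomass,pb,cb,ae,ee,ee_fixed,ba,immigration,emigration,is_homeotherm,retention
1,Large phytoplankton,producer,1.00,45.753,215.00,,,0.980,false,,,,false,
2,Small phytoplankton,producer,1.00,6.230,215.00,,,0.945,false,,,,false,
3,Micro-zooplankton,consumer,2.00,16.219,150.00,428.57,0.8,0.900,true,,,,false,
4,Large copepods,consumer,2.25,6.552,15.00,60.00,0.8,0.744,false,,,,false,
5,Small copepods,consumer,2.35,26.443,37.00,148.00,0.8,0.419,false,,,,false,
6,Small invertebrate larvae,consumer,2.35,4.813,37.00,148.00,0.8,0.573,false,,,,false,
7,Pteropods,consumer,2.53,0.272,15.00,50.00,0.8,0.759,false,,,,false,
8,Pelagic amphipods,consumer,2.65,0.662,14.00,56.00,0.8,0.734,false,,,,false,
9,Pelagic shrimp,consumer,3.27,18.939,3.00,12.00,0.8,0.885,false,,,,false,
10,Other macro-zooplankton,consumer,2.88,6.309,10.00,40.00,0.8,0.726,false,,,,false,
11,Small jellyfish (net-feeders),consumer,2.40,1.671,45.00,150.00,0.8,0.021,false,,,,false,
12,Small jellyfish (carnivores),consumer,3.48,0.054,20.00,66.67,0.8,0.023,false,,,,false,
13,Large jellyfish,consumer,3.08,0.101,15.00,60.00,0.8,0.079,false,,,,false,
14,Pyrosomes,consumer,2.08,15.976,45.00,150.00,0.8,0.001,false,,,,false,
15,E. pacifica,consumer,2.30,32.294,6.00,24.00,0.8,0.932,false,,,,false,
16,T. spinifera,consumer,2.30,10.234,7.00,28.00,0.8,0.799,false,,,,false,
17,Small cephalopod aggregate,consumer,3.63,2.640,3.00,12.00,0.8,0.850,true,,,,false,
18,Cephalopod humboldt,consumer,4.36,0.005,2.75,11.00,0.8,0.969,false,,,,false,
19,Smelt aggregate,consumer,3.65,7.383,1.80,7.20,0.8,0.821,false,,,,false,
20,Shad,consumer,3.34,2.081,1.13,4.53,0.8,0.900,true,,,,false,
21,Sardine,consumer,3.11,1.841,1.13,4.53,0.8,0.966,false,,,,false,
22,Herring,consumer,3.17,4.099,1.80,7.20,0.8,0.943,false,,,,false,
23,Anchovy,consumer,3.19,3.038,1.80,7.20,0.8,0.860,false,,,,false,
24,Saury,consumer,3.75,0.130,1.13,4.53,0.8,0.775,false,,,,false,
25,Coho yearling,consumer,4.28,0.222,1.80,7.20,0.8,0.933,false,,,,false,
26,Chinook yearling spring-run,consumer,4.20,0.110,1.13,4.53,0.8,0.881,false,,,,false,
27,Chinook yearling fall-run,consumer,4.24,0.080,1.13,4.53,0.8,0.834,false,,,,false,
28,Chinook subyearling fall-run early,consumer,3.94,0.015,1.80,7.20,0.8,0.841,false,,,,false,
29,Chinook subyearling fall-run late,consumer,4.19,0.094,1.80,7.20,0.8,0.820,false,,,,false,
30,Other Chinook yearling,consumer,4.31,0.014,1.13,4.53,0.8,0.956,false,,,,false,
31,Other Chinook subyearling,consumer,4.07,0.057,1.80,7.20,0.8,0.961,false,,,,false,
32,Other juvenile salmon,consumer,3.46,0.028,1.80,7.20,0.8,0.855,false,,,,false,
33,Mesopelagic fish aggregate,consumer,3.36,1.245,1.75,7.00,0.8,0.850,true,,,,false,
34,Planktivorous rockfish,consumer,3.76,6.420,0.13,1.25,0.8,0.952,false,,,,false,
35,Coho,consumer,4.17,0.230,1.80,10.59,0.8,0.739,false,,,,false,
36,Chinook,consumer,4.07,0.112,0.75,4.41,0.8,0.892,false,,,,false,
37,Other salmon aggregate,consumer,3.98,0.019,1.90,11.18,0.8,0.756,false,,,,false,
38,Shark aggregate,consumer,4.73,0.017,0.20,3.33,0.8,0.788,false,,,,false,
39,Jack mackerel,consumer,3.64,21.395,0.23,2.30,0.8,0.103,false,,,,false,
40,Pacific mackerel,consumer,3.49,0.857,0.76,7.60,0.8,0.848,false,,,,false,
41,Piscivorous rockfish,consumer,3.88,3.072,0.17,1.72,0.8,0.980,false,,,,false,
42,Dogfish aggregate,consumer,4.21,3.475,0.20,2.50,0.8,0.272,false,,,,false,
43,Hake,consumer,3.65,18.500,0.35,3.54,0.8,0.987,false,,,,false,
44,Tuna aggregate,consumer,4.29,0.200,0.30,3.00,0.8,0.893,false,,,,false,
45,Sablefish,consumer,4.16,1.787,0.23,2.30,0.8,0.952,false,,,,false,
46,Hexagrammidae (lingcod greenling),consumer,4.43,0.722,0.30,3.00,0.8,0.905,false,,,,false,
47,Flatfish (water-column feeders),consumer,4.29,3.797,0.28,1.38,0.8,0.817,false,,,,false,
48,Skates & rays,consumer,3.71,2.769,0.23,2.30,0.8,0.266,false,,,,false,
49,Misc. small benthic fishes,consumer,3.33,8.900,0.40,4.00,0.8,0.900,true,,,,false,
50,Benthivorous rockfish,consumer,3.67,7.987,0.07,0.70,0.8,0.811,false,,,,false,
51,Gadidae (cod haddock pollock),consumer,3.48,0.120,0.35,3.50,0.8,0.838,false,,,,false,
52,Flatfish (benthic feeders),consumer,3.16,11.878,0.30,3.00,0.8,0.684,false,,,,false,
53,Flatfish (small),consumer,3.45,7.968,0.38,1.90,0.8,0.919,false,,,,false,
54,Grenadier,consumer,3.62,1.206,0.20,1.00,0.8,0.066,false,,,,false,
55,Juvenile rockfish,consumer,3.51,1.202,2.70,10.80,0.8,0.930,false,,,,false,
56,Juvenile fish (other),consumer,3.26,5.991,2.70,10.80,0.8,0.735,false,,,,false,
57,Juvenile fish (chondrichthyes),consumer,3.44,0.535,2.70,10.80,0.8,0.850,true,,,,false,
58,Infauna,consumer,2.00,80.000,4.50,18.00,0.8,0.973,false,,,,false,
59,Pandalus spp.,consumer,2.91,14.257,3.00,12.00,0.8,0.903,false,,,,false,
60,Other epibenthic shrimp (Caridea),consumer,2.81,12.950,4.20,16.80,0.8,0.850,true,,,,false,
61,Mysids,consumer,2.83,2.637,22.00,110.00,0.8,0.850,true,,,,false,
62,Echinoderms,consumer,2.07,21.361,1.21,6.05,0.8,0.850,true,,,,false,
63,Benthic amphipods isopods and cumaceans,consumer,2.05,7.158,21.50,107.50,0.8,0.850,true,,,,false,
64,Bivalves,consumer,2.03,64.450,1.30,6.50,0.8,0.850,true,,,,false,
65,Misc. epifauna (suspension feeders),consumer,2.14,3.828,7.40,37.00,0.8,0.850,true,,,,false,
66,Dungeness crab,consumer,3.27,5.109,1.50,6.00,0.8,0.952,false,,,,false,
67,Tanner crab,consumer,2.99,0.869,1.00,4.00,0.8,0.939,false,,,,false,
68,Misc. epifauna (carnivorous),consumer,2.67,31.550,3.00,15.00,0.8,0.850,true,,,,false,
69,Sooty shearwaters,consumer,4.31,0.017,0.10,73.00,0.8,0.014,false,,,,true,
70,Common murre,consumer,4.37,0.015,0.17,72.00,0.8,0.210,false,,,,true,
71,Gulls & terns,consumer,3.79,0.001,0.17,73.00,0.8,0.774,false,,,,true,
72,Alcids,consumer,3.90,0.001,0.17,110.00,0.8,0.084,false,,,,true,
73,Large pelagic seabirds,consumer,4.08,0.001,0.07,75.00,0.8,0.128,false,,,,true,
74,Other pelagic seabirds,consumer,4.29,0.001,0.10,73.00,0.8,0.046,false,,,,true,
75,Coastal seabirds (divers),consumer,4.29,0.001,0.16,73.00,0.8,0.218,false,,,,true,
76,Storm-petrels,consumer,3.86,0.0001,0.12,144.00,0.8,0.072,false,,,,true,
77,Gray whales,consumer,3.72,0.146,0.06,8.90,0.8,0.002,false,,,,true,
78,Baleen whales,consumer,3.69,0.572,0.04,7.60,0.8,0.002,false,,,,true,
79,Small pinnipeds,consumer,4.55,0.024,0.08,8.30,0.8,0.034,false,,,,true,
80,Sea lions,consumer,4.64,0.049,0.07,24.00,0.8,0.279,false,,,,true,
81,Northern elephant seals,consumer,4.49,0.062,0.07,24.00,0.8,0.219,false,,,,true,
82,Small toothed whales,consumer,4.44,0.072,0.10,25.80,0.8,0.112,false,,,,true,
83,Large toothed whales,consumer,4.57,0.067,0.05,6.61,0.8,0.003,false,,,,true,
84,Other killer whales,consumer,4.94,0.0004,0.03,11.16,0.8,0.000,false,,,,true,
85,Southern resident killer whales,consumer,5.13,0.005,0.03,11.16,0.8,0.000,false,,,,true,
86,Invertebrate eggs,detritus,1.00,0.00002,0.00,0.00,,0.225,false,,,,false,
87,Fish eggs,detritus,1.00,1.906,0.00,0.00,,0.421,false,,,,false,
88,Pelagic detritus,detritus,1.00,10.000,0.00,0.00,,0.525,false,,,,false,
89,Fishery offal,detritus,1.00,5.000,0.00,0.00,,0.684,false,,,,false,
90,Benthic detritus,detritus,1.00,10.000,0.00,0.00,,0.885,false,,,,false,
91,Dredge,fleet,3.04,,,,,,false,,,,false,
92,Hook & line,fleet,5.16,,,,,,false,,,,false,
93,Other gear,fleet,4.57,,,,,,false,,,,false,
94,Net,fleet,4.34,,,,,,false,,,,false,
95,Pot & trap,fleet,4.53,,,,,,false,,,,false,
96,Trolling,fleet,5.23,,,,,,false,,,,false,
97,Trawl (non-shrimp),fleet,4.67,,,,,,false,,,,false,
98,Shrimp trawls,fleet,3.97,,,,,,false,,,,false,
99,Recreational fishery,fleet,5.07,,,,,,false,,,,false,
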