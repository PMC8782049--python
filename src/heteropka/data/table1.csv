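no,name,formula,pka1,acd_pka1,acd_pka1_unc,pka2,acd_pka2,acd_pka2_unc
1,azauracil,C3H3N3O2,-,-4.4,0.2,-,7.8,0.2
2,aziridine,C2H5N,7.98 [32]; 8.05 [33],8.1,0.2,-,-,-
3,creatinine,C4H7N3O,4.8 [34],4.8,0.1,-,-,-
4,cytosine,C4H5N3O,4.32 [30]; 4.58 [35]; 4.6 [31],4.4,0.1,13 [33]; 12.15 [36],12.3,0.1
5,flucytosine,C4H3FN2O2,3.26 [34],2.6,0.1,-,10.5,0.1
6,imidazole,C3H4N2,"7.15 [33]; 6.99 [34,35]",7.2,0.6,14.44 [33],13.9,0.1
7,1-methylimidazole,C4H6N2,6.95 [34],7.0,0.1,N/A,-,-
8,4-methylimidazole,C4H6N2,7.55 [35],7.7,0.6,-,14.3,0.1
9,isocytosine,C4H5N3O,4.01 [34],3.4,0.5,9.42 [36],9.6,0.4
10,isoxazole,C3H6NO,-2.0 [34],-2.0,0.5,N/A,-,-
11,maleimide,C4H3NO2,-,-5.7,0.2,9.46 [37],8.5,0.2
12,morpholine,C4H9NO,8.492 [35],9.0,0.2,N/A,-,-
13,piperidine,C5H11N,11.12 [35],10.4,0.1,-,-,-
14,piperazine,C4H10N2,9.78 [35]; 9.73 [34],9.6,0.1,-,-,-
15,1-methylpiperazine,C5H12N2,10.19 [35],9.3,0.1,-,-,-
16,oxazole,C3H6NO,0.8 [34],1.0,0.1,N/A,-,-
17,pyrazine,C4H4N2,0.65 [34],1.2,0.1,N/A,-,-
18,pyrazole,C3H4N2,2.61 [35],2.8,0.1,14.21 [33],14.0,0.5
19,pyridazine,C4H43N2,2.3 [32],3.1,0.1,N/A,-,-
20,pyridine,C5H5N,5.23 [34],5.2,0.1,N/A,-,-
21,pyrimidine,C4H4N2,1.3 [32],1.8,0.1,N/A,-,-
22,pyrrole,C4H5N,-3.8 [34],-0.3,0.5,17.0 [33],17.0,0.5
23,pyrrolidine,C4H9N,"12.10 [33]; 11.31 [34,35]",10.5,0.1,-,-,-
24,succinimide,C4H5NO2,-,-4.4,0.2,"9.62 [34,35]; 9.68 [36]",9.6,0.1
25,thymine,C5H6N2O2,-,-4.1,0.4,9.9 [33]; 9.79 [35]; 9.44 [34],9.2,0.1
26,uracil,C4H4N2O2,-,-4.2,0.1,"9.43 [38]; 9.45 [34,36]",8.9,0.1
27,5-bromouracil,C4H3BrN2O2,-,-,-,7.91 [38],6.8,0.1
28,5-chlorouracil,C4H3CIN2O2,-,-,-,7.92 [38],6.8,0.1
29,fluorouracil,C4H4FN3O,-,-,-,8.04 [30]; 8.00 [39]; 7.93 [38],6.7,0.1
30,5-formyluracil,C5H4N2O3,-,-,-,6.84 [38],7.3,0.1
31,5-nitrouracil,C4H3N3O4,-,-,-,5.3 [38],5.2,0.1
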