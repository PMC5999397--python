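sample_id,name,grid_type,intentionally_thick,affinity_overlay,no_interface_interaction,t_center,t_edge,t_substrate,layers_center,layers_edge,layers_substrate,preferred_orientation,min_layer_distance,ice_bottom,ice_top,codes_bottom_center,codes_bottom_edge,codes_top_center,codes_top_edge,tilts_center,tilts_edge
1,32 kDa Kinase,Carbon Spotiton,0,0,0,65,45,--,0,0,0,unknown,<5,C2,C2,A:B1|B2|B3,A:B1|B2|B3,A:B1|B2|B3,A:B1|B2|B3,8;8,10;10
2,32 kDa Kinase,Gold Spotiton,0,0,0,30,--,--,0,--,--,unknown,<5,C1|C2,C1|C2,A:B1|B2|B3,--,A:B1|B2|B3,--,4-8;4-8,
3,Insulin Receptor,Gold Spotiton,0,0,0,55,--,--,1-2,--,--,no,5,C2|C3,C2|C3,A:B1|B2|B3,--,A:B1|B2|B3,--,3-5;3-5,
4,Hemagglutinin,Carbon Spotiton,0,0,0,25-95,100-210,--,0|2,2,--,some,5,C3|C4,C3|C4,A2:none,A:B3,A2:none / A:B3,A:B3,3-7;3-7;7,5;3;5-7
5,HIV-1 Trimer Complex 1,Carbon Spotiton,0,0,0,75-210,--,--,2,--,--,yes,5-10,C1|C2|C3,C1|C2|C3,"A2:B1,B3",--,"A2:B1,B3",--,1-5;1-5,
6,HIV-1 Trimer Complex 1,Gold Spotiton,0,0,0,20,--,--,1,--,--,some,5,C2,C2,A2:B3,--,A2:B3,--,6;6,
7,HIV-1 Trimer Complex 2,Carbon Spotiton,0,0,0,190,265,--,2,2,2,yes,5,C1|C2,C1|C2,A:B2|B3,A:B2|B3,A:B2|B3,A:B2|B3,1;1,3;3
8,147 kDa Kinase,Gold Spotiton,0,0,0,15,--,--,1,--,--,unknown,<5,C2|C3,C2|C3,A:B2|B3,--,A:B2|B3,--,0;0,
9,150 kDa Protein,Holey Carbon Spotiton,0,0,0,35,70,--,2,2,2,some,<5,C2|C3,C2|C3,A:B2|B3,A:B2|B3,A:B2|B3,A:B2|B3,7-10;7,8;9
10,Stick-like Protein 1,Carbon Spotiton,1,0,0,80,--,--,1,--,--,no,<5,C2,C2,"A+A2:B4,B5",--,"A2:B4,B5",--,10;10,
11,Stick-like Protein 2 (150 kDa),Carbon CFlat,1,0,0,100,100,--,1,1,--,unknown,5,--,--,"A2:B3,B4,B5","A2:B3,B4,B5","A2:B3,B4,B5","A2:B3,B4,B5",7;7,7;7
12,Stick-like Protein 2,Gold Spotiton,1,0,0,135-190,--,--,1,--,--,some,5,C2|C3,C2|C3,A2:B3,--,A2:B3,--,0;0,
13,Neural Receptor,Carbon Spotiton,1,0,0,60-90,--,--,1,--,--,yes,5,C2|C3,C2|C3,A2:B3,--,A2:none,--,3-10;3-10,
14,Neural Receptor,Carbon Spotiton,1,0,0,80-90,100-140,135,1,1,1,yes,5,C3,C3,--,A2:none / A2:B3,--,A2:B3 / A2:none,,2-7;5;7;7
15,200 kDa Protein,CFlat Carbon + Gold mesh,0,0,0,40-60,95,110,1,1,2,no,5,C3,C3,A:B2|B3,A:B2|B3,none / A:B2|B3,A:none,2;2,4;11
16,"Small, Popular Protein",Carbon Spotiton,0,0,0,30,70,--,1,2,2,no,5,C2,C3,A:B2|B3,A:B2|B3,A:B2|B3,A:B2|B3,6;6,9;1
17,Glycoprotein with Bound Lipids (deglycosylated),Carbon Spotiton,0,0,0,15,90,130,1,2,2,yes,<5,C3,C3,A:B3,A:B3,A:B3,A:B3,4;4,10;11
18,Glycoprotein with Bound Lipids (glycosylated),Gold Spotiton,1,0,0,155,--,--,2,--,--,some,<5,C2|C3,C2|C3,A:B3,--,A:B3,--,10;4,
19,Lipo-protein,Holey Carbon,0,0,0,0-95,85-100,--,uniform,uniform,--,unknown,5,C3+C4,C3+C4,none / A:B2,A:B3,none / A:B2,A:B3,3;5,11;11
20,GPCR,Carbon Spotiton,0,0,0,25,--,--,1,2,--,no,5,C3,C3,A:B2|B3,A:B2|B3,A:B2|B3,A:B2|B3,3;3,
21,Rabbit Muscle Aldolase (1 mg/mL),Gold Spotiton,0,0,0,15,50,--,1,2,--,no,<5,C3,C3,A:B2|B3,A:B2|B3,A:B2|B3,A:B2|B3,3-9;3-9,6;10
22,Rabbit Muscle Aldolase (6 mg/mL),Carbon Spotiton,0,0,0,60-110,75-130,85,2,2,2,some,5,C2|C3,C2|C3,"A:B1,B2|B3","A:B1,B2|B3","A:B1,B2|B3","A:B1,B2|B3",5;5,5;5
23,Un-named Protein,Holey Carbon,0,0,0,35,--,60,1,--,2,yes,5,C2|C3,C2|C3,A:B3,--,A:B3,--,0-3;0-3,
24,Un-named Protein,--,0,0,0,--,--,--,--,--,--,unknown,--,C3,C3,A:B3,A:B3,A:B3,A:B3,2;2,4-6;4-9
25,Protein in Nanodisc (0.58 mg/mL),Gold Spotiton,0,0,1,30,65,--,1-2,2,--,no,5-10,C2|C3,C2|C3,A:B2,A:B2,A:B2,A:B2,8-10;8-10,8-10;8-10
26,IDE,Carbon Spotiton,0,0,0,25,60,95,1,2,2,unknown,5,C3,C3,"A2:B2|B3,B4,B5","A2:B1,B2|B3,B4,B5","A2:B2|B3,B4,B5","A2:B1,B2|B3,B4,B5",0;0,5;2
27,IDE,Gold Spotiton,0,0,0,40,--,--,1,--,--,no,5-10,C2,C2,A:B2|B3,--,A:B2|B3,--,0-4;0-4,
28,"Small, Helical Protein",Gold Spotiton,0,0,0,50,75,--,1,2,--,some,5,C3,C3,A:B2|B3,A:B2|B3,A:B2|B3,A:B2|B3,5;5,3;7
29,300 kDa Protein,Carbon Spotiton,0,0,0,30,100,--,1,2,2,no,5,C3,C3,A|A2:B2|B3,A|A2:B2|B3,A|A2:B2|B3,A|A2:B2|B3,7;7,13;9
30,GDH,Holey Carbon,0,0,0,30,85,100,1,1,3,some,5,C2,C3,A:B3,"A:B1,B3",A:B3,"A:B1,B3",10;10,1;16
31,GDH,Holey Carbon,0,0,0,60,120,140,1,2,3,yes,5,C3,C2,A:B3,"A:B1,B3",A:B3,"A:B1,B3",,10;2
32,GDH (2.5 mg/mL)+0.001% DDM,Carbon Spotiton,0,0,0,50,180,190,1,2,--,yes,<5,C2,C3,A:B3,"A:B1,B3",A:B3,"A:B1,B3",4;4,7;6
33,DnaB Helicase-helicase Loader,Gold Quantifoil,0,0,0,50-55,80-100,--,1,2,--,no,5,C3,C2,A:B2|B3,A:B2|B3,A:B2|B3,A:B2|B3,1;1,4;1
34,Apoferritin,Gold Spotiton,0,0,0,25-30,--,--,1,--,--,no,5,C2|C3,C2|C3,A2:B2|B3,--,A2:B2|B3,--,4-6;4-6,
35,Apoferritin,Gold Spotiton,0,0,0,25,--,--,1,--,--,no,5,C2|C3,C2|C3,A2:B2|B3,--,A2:B2|B3,--,4-12;4-12,
36,Apoferritin,Holey Carbon Spotiton,0,0,0,30,125,135,1,2,2,no,5,C3,C3,A2:B3,"A2:B1,B3",A2:B3,"A2:B1,B3",5;5,10;3
37,Apoferritin (1.25 mg/mL),Holey Carbon Spotiton,0,0,0,30-50,100,105,1,2,2,no,5,C3,C3,A2:B2|B3,"A2:B1,B2|B3",A2:B2|B3,"A2:B1,B2|B3",4-7;4,6;4
38,Apoferritin (0.5 mg/mL),Holey Gold Spotiton,0,0,0,25-30,55,--,1,2,--,no,<5,C2|C3,C2|C3,A2:B2|B3,--,A2:B2|B3,--,5;1,
39,Apoferritin with 0.5 mM TCEP,Carbon Spotiton,0,0,0,40-90,145-175,--,1-2,2,1,no,5,C3,C3,A:B2|B3,"A:B1,B2|B3",A:B2|B3,"A:B1,B2|B3",3;3,5-9;2-8
40,Protein with Carbon Over Holes,Carbon Quantifoil,0,1,0,110,70-100,--,1,1,--,some,5-10,C2,C1|C2,"Carbon:B1,B3","Carbon:B1,B3",A:B3,A:B3,5;5,5-9;5
41,Protein and DNA Strands with Carbon Over Holes,Carbon Quantifoil,0,1,0,60,--,--,1,--,--,some,5-10,C2|C3,C2,A:none,--,"Carbon:B1,B3",--,2-3;2-3,
42,T20S Proteasome,Holey Carbon,0,0,0,35,115,120,1,2,3,some,<5,C3,C2,A:B3,"A:B1,B3",A:B3,"A:B1,B3",3;3,14;3
43,T20S Proteasome,Holey Carbon,0,0,0,125,140-160,150,2,2,2,some,5,C2,C3,A:B3,A:B3,"A:B1,B3","A:B1,B3",2-5;5-7,2-5;5-7
44,T20S Proteasome,Gold Quantifoil,0,0,0,50-75,--,--,1,--,--,some,5,C3,C2,"A:B1,B3",--,A:B3,--,11;11,
45,Mtb 20S Proteasome,Carbon Spotiton,0,0,0,35,80,115,0,1,1,no,5-10,C3,C3,--,"A:B1,B2|B3",--,"A:B1,B2|B3",,6;11
46,Protein on Streptavidin,Holey Carbon,0,1,1,20-100,80-120,--,0-2,1-2,--,no,10,C1|C2|C3,C1|C2|C3,Streptavidin:B2 / Streptavidin:none,Streptavidin|A2:B2,Streptavidin:B2 / Streptavidin:none,Streptavidin:B2,0;12;0;12,12;13-14
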