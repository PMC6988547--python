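population,region,egu,form,size_class,n,delta_j,immediate_threat,management_plan,protected_area,introduced,low_vitality,collaboration
1R,N,Rueckland der Mecklenburgischen Seenplatte,terr,medium,27,0.3884,0,0,0,0,0,0
2R,N,Mecklenburgische Seenplatte,terr,medium,28,0.36,0,0,0,0,0,0
3R,N,Mecklenburgische Seenplatte,terr,large,29,0.375,0,0,0,0,0,0
4R,N,Rueckland der Mecklenburgischen Seenplatte,terr,small,7,0.3136,0,0,0,0,0,0
5R,N,Mecklenburgische Seenplatte,terr,medium,25,0.447,0,0,1,0,0,0
7R,N,Westfaelische Tieflandbucht,terr,small,26,0.3064,0,0,0,0,0,0
8R,N,Westfaelische Tieflandbucht,terr,medium,30,0.4104,0,0,0,0,0,0
9R,N,Duemmer-Geestniederung,terr,medium,30,0.2798,0,1,0,0,0,1
10R,N,Schleswig-Holsteinisches Huegelland,terr,medium,29,0.3798,0,0,1,1,0,1
11R,N,Rueckland der Mecklenburgischen Seenplatte,terr,medium,30,0.2952,0,0,0,0,1,0
12R,N,Elbtalniederung,terr,large,26,0.3409,0,0,0,0,0,0
13R,N,Ostbrandenburgisches Heide- und Seengebiet,terr,large,30,0.4394,0,0,0,0,0,0
14R,N,Altmark,terr,small,15,0.3598,0,0,0,0,0,1
15R,S,Unterbayerisches Huegelland,terr,small,29,0.2829,0,0,0,0,0,0
16R,S,Schwaebisch-Oberbayerische Voralpen,aqu,medium,30,0.3155,0,0,0,0,0,0
17R,S,Schwaebisch-Oberbayerische Voralpen,terr,small,28,0.3914,0,0,0,0,1,0
18R,S,Unterbayerisches Huegelland,terr,medium,27,0.2498,0,0,0,0,0,0
19R,S,Voralpines Huegel- und Moorland,aqu,small,30,0.3617,0,0,0,0,0,0
20R,S,Voralpines Huegel- und Moorland,aqu,medium,29,0.2966,0,0,0,0,0,0
21R,S,Schwaebisch-Oberbayerische Voralpen,aqu,medium,30,0.4754,0,0,0,0,0,0
22R,S,Schwaebisch-Oberbayerische Voralpen,aqu,large,29,0.4902,0,0,0,0,0,0
23R,S,Schwaebisch-Oberbayerische Voralpen,aqu,medium,30,0.4161,0,0,0,0,0,0
24R,S,Donau-Iller-Lech-Platten,aqu,large,29,0.3136,0,0,0,0,0,0
25R,S,Voralpines Huegel- und Moorland,aqu,medium,28,0.3845,0,0,0,0,0,0
26R,S,Noerdliche Kalkhochalpen,terr,large,29,0.342,0,0,0,0,0,0
27R,S,Voralpines Huegel- und Moorland,terr,large,26,0.268,0,0,1,0,0,0
28R,S,Voralpines Huegel- und Moorland,terr,small,9,0.3732,0,0,0,0,0,0
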