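FF
     RDKit          2D

 25 26  0  0  0  0  0  0  0  0999 V2000
    3.7500   -6.4952    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.5000   -5.1962    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    6.0000   -5.1962    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.7500   -3.8971    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    4.5000   -2.5981    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    6.0000   -2.5981    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    3.7500   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    5.0490   -0.5490    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.4510   -2.0490    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.0000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.7500   -1.2990    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -3.7500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.0000    2.5981    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.7500    3.8971    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.2500    3.8971    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -6.0000    5.1962    0.0000 Cl  0  0  0  0  0  0  0  0  0  0  0  0
   -6.0000    2.5981    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.2500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  2  4  1  0
  4  5  1  0
  5  6  2  0
  5  7  1  0
  7  8  1  0
  7  9  1  0
  7 10  1  0
 10 11  1  0
 11 12  2  0
 12 13  1  0
 13 14  2  0
 14 15  1  0
 15 16  2  0
 15 17  1  0
 17 18  2  0
 18 19  1  0
 19 20  2  0
 20 21  1  0
 20 22  1  0
 22 23  2  0
 14 24  1  0
 24 25  2  0
 25 11  1  0
 23 17  1  0
M  END
>  <id>  (1) 
FF

>  <name>  (1) 
fenofibrate

>  <role_tag>  (1) 
control

$$$$
FFA
     RDKit          2D

 22 23  0  0  0  0  0  0  0  0999 V2000
    5.0490   -0.5490    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.7500   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.4510   -2.0490    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.0000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.7500   -1.2990    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -3.7500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.0000    2.5981    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.7500    3.8971    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.2500    3.8971    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -6.0000    5.1962    0.0000 Cl  0  0  0  0  0  0  0  0  0  0  0  0
   -6.0000    2.5981    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.2500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.5000   -2.5981    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    6.0000   -2.5981    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    3.7500   -3.8971    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  2  4  1  0
  4  5  1  0
  5  6  2  0
  6  7  1  0
  7  8  2  0
  8  9  1  0
  9 10  2  0
  9 11  1  0
 11 12  2  0
 12 13  1  0
 13 14  2  0
 14 15  1  0
 14 16  1  0
 16 17  2  0
  8 18  1  0
 18 19  2  0
  2 20  1  0
 20 21  2  0
 20 22  1  0
 19  5  1  0
 17 11  1  0
M  END
>  <id>  (2) 
FFA

>  <name>  (2) 
fenofibric acid

>  <role_tag>  (2) 
control

$$$$
CAF
     RDKit          2D

 14 15  0  0  0  0  0  0  0  0999 V2000
   -2.9499    4.2246    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.8351    3.2209    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
   -2.1470    1.7537    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.5736    1.2902    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -1.0323    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.3943    1.2135    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2760    0.0000    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    0.3943   -1.2135    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.0323   -0.7500    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
   -2.2458   -1.6317    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7062    2.6807    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    2.1328    3.1443    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.4086    3.6844    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.0967    5.1517    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  2  0
  3  5  1  0
  5  6  2  0
  6  7  1  0
  7  8  2  0
  8  9  1  0
  9 10  1  0
  6 11  1  0
 11 12  1  0
 11 13  1  0
 13 14  2  0
 13  2  1  0
  9  5  1  0
M  END
>  <id>  (3) 
CAF

>  <name>  (3) 
caffeine

>  <role_tag>  (3) 
control

$$$$
TMZ
     RDKit          2D

 14 15  0  0  0  0  0  0  0  0999 V2000
   -2.9499    4.2246    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.8351    3.2209    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
   -0.4086    3.6844    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    0.7062    2.6807    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    0.3943    1.2135    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2760    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.7760    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.5260   -1.2990    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    3.5260    1.2990    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    0.3943   -1.2135    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
   -1.0323   -0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.0323    0.7500    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
   -2.1470    1.7537    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.5736    1.2902    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  7  1  0
  7  8  1  0
  7  9  2  0
  6 10  1  0
 10 11  2  0
 11 12  1  0
 12 13  1  0
 13 14  2  0
 13  2  1  0
 12  5  1  0
M  END
>  <id>  (4) 
TMZ

>  <name>  (4) 
temozolomide

>  <role_tag>  (4) 
control

$$$$
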