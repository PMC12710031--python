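index,name,R,G,B,L,a,b,row,col
1,dark skin,115,82,68,38.0168,11.7960,13.6661,1,1
2,light skin,194,150,130,65.6673,13.6733,16.9012,1,2
3,blue sky,98,122,157,50.6276,0.3687,-21.5969,1,3
4,foliage,87,108,67,42.9981,-15.8766,20.4528,1,4
5,blue flower,133,128,177,55.6837,12.7612,-25.1658,1,5
6,bluish green,103,189,170,70.9940,-30.6396,1.5406,1,6
7,orange,214,126,44,61.1362,28.1038,56.1314,2,1
8,purplish blue,80,91,166,41.1203,17.4067,-41.8780,2,2
9,moderate red,193,90,99,51.3287,42.0951,14.8850,2,3
10,purple,94,60,108,31.1005,24.3534,-22.0964,2,4
11,yellow green,157,188,64,71.8963,-28.1046,56.9584,2,5
12,orange yellow,224,163,46,71.0379,12.6018,64.9156,2,6
13,blue,56,61,150,30.3502,26.4315,-49.6663,3,1
14,green,70,148,73,55.0332,-40.1378,32.2984,3,2
15,red,175,54,60,41.3450,49.3026,24.6612,3,3
16,yellow,231,199,31,80.7043,-3.6645,77.5480,3,4
17,magenta,187,86,149,51.1433,48.1463,-15.2800,3,5
18,cyan,8,133,161,51.1495,-19.7323,-23.3696,3,6
19,white,243,243,242,95.8167,-0.1786,0.4851,4,1
20,neutral 8,200,200,200,80.6041,-0.0020,0.0039,4,2
21,neutral 6.5,160,160,160,65.8678,-0.0017,0.0033,4,3
22,neutral 5,122,122,121,51.1948,-0.2012,0.5486,4,4
23,neutral 3.5,85,85,85,36.1459,-0.0011,0.0021,4,5
24,black,52,52,52,21.7043,-0.0008,0.0015,4,6
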