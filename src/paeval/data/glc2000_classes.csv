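code,label,status
1,Tree cover broadleaved evergreen,natural
2,Tree cover broadleaved deciduous closed,natural
3,Tree cover broadleaved deciduous open,natural
4,Tree cover needle-leaved evergreen,natural
5,Tree cover needle-leaved deciduous,natural
6,Tree cover mixed leaf type,natural
7,Tree cover regularly flooded fresh water,natural
8,Tree cover regularly flooded saline water,natural
9,Mosaic tree cover / other natural vegetation,natural
10,Tree cover burnt,natural
11,Shrub cover closed-open evergreen,natural
12,Shrub cover closed-open deciduous,natural
13,Herbaceous cover closed-open,natural
14,Sparse herbaceous or sparse shrub cover,natural
15,Regularly flooded shrub and/or herbaceous cover,natural
16,Cultivated and managed areas,converted
17,Mosaic cropland / tree cover / other natural vegetation,converted
18,Mosaic cropland / shrub or grass cover,converted
19,Bare areas,natural
20,Water bodies,natural
21,Snow and ice,natural
22,Artificial surfaces and associated areas,converted
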