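code,label,status
11,Post-flooding or irrigated croplands,converted
14,Rainfed croplands,converted
20,Mosaic cropland (50-70%) / vegetation (20-50%),converted
30,Mosaic vegetation (50-70%) / cropland (20-50%),converted
40,Closed to open broadleaved evergreen or semi-deciduous forest,natural
50,Closed broadleaved deciduous forest,natural
60,Open broadleaved deciduous forest,natural
70,Closed needleleaved evergreen forest,natural
90,Open needleleaved deciduous or evergreen forest,natural
100,Closed to open mixed broadleaved and needleleaved forest,natural
110,Mosaic forest or shrubland / grassland,natural
120,Mosaic grassland / forest or shrubland,natural
130,Closed to open shrubland,natural
140,Closed to open herbaceous vegetation,natural
150,Sparse vegetation,natural
160,Closed to open broadleaved forest regularly flooded (fresh water),natural
170,Closed broadleaved forest permanently flooded (saline water),natural
180,Closed to open grassland or woody vegetation regularly flooded,natural
190,Artificial surfaces and associated areas,converted
200,Bare areas,natural
210,Water bodies,natural
220,Permanent snow and ice,natural
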