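province,year,chrdi
Beijing,2016,2.914
Beijing,2017,2.821
Beijing,2018,3.275
Beijing,2019,3.495
Beijing,2020,3.628
Tianjin,2016,1.905
Tianjin,2017,1.986
Tianjin,2018,2.092
Tianjin,2019,2.143
Tianjin,2020,2.275
Hebei,2016,1.087
Hebei,2017,0.970
Hebei,2018,1.226
Hebei,2019,1.247
Hebei,2020,1.326
Shanxi,2016,0.961
Shanxi,2017,0.858
Shanxi,2018,1.015
Shanxi,2019,1.037
Shanxi,2020,1.087
Inner Mongolia,2016,0.300
Inner Mongolia,2017,0.280
Inner Mongolia,2018,0.327
Inner Mongolia,2019,0.331
Inner Mongolia,2020,0.351
Liaoning,2016,0.993
Liaoning,2017,0.913
Liaoning,2018,1.060
Liaoning,2019,1.045
Liaoning,2020,1.092
Jilin,2016,0.693
Jilin,2017,0.638
Jilin,2018,0.761
Jilin,2019,0.758
Jilin,2020,0.879
Heilongjiang,2016,0.490
Heilongjiang,2017,0.451
Heilongjiang,2018,0.516
Heilongjiang,2019,0.535
Heilongjiang,2020,0.569
Shanghai,2016,3.720
Shanghai,2017,3.624
Shanghai,2018,4.062
Shanghai,2019,4.208
Shanghai,2020,4.454
Jiangsu,2016,1.530
Jiangsu,2017,1.369
Jiangsu,2018,1.731
Jiangsu,2019,1.820
Jiangsu,2020,1.967
Zhejiang,2016,1.379
Zhejiang,2017,1.382
Zhejiang,2018,1.507
Zhejiang,2019,1.575
Zhejiang,2020,1.701
Anhui,2016,0.940
Anhui,2017,0.814
Anhui,2018,1.046
Anhui,2019,1.095
Anhui,2020,1.291
Fujian,2016,0.926
Fujian,2017,0.844
Fujian,2018,1.002
Fujian,2019,1.034
Fujian,2020,1.129
Jiangxi,2016,0.853
Jiangxi,2017,0.722
Jiangxi,2018,0.932
Jiangxi,2019,0.965
Jiangxi,2020,1.048
Shandong,2016,1.541
Shandong,2017,1.361
Shandong,2018,1.692
Shandong,2019,1.726
Shandong,2020,1.834
Henan,2016,1.310
Henan,2017,1.116
Henan,2018,1.440
Henan,2019,1.467
Henan,2020,1.628
Hubei,2016,1.125
Hubei,2017,0.920
Hubei,2018,1.182
Hubei,2019,1.177
Hubei,2020,1.306
Hunan,2016,1.117
Hunan,2017,0.895
Hunan,2018,1.188
Hunan,2019,1.284
Hunan,2020,1.326
Guangdong,2016,1.205
Guangdong,2017,1.146
Guangdong,2018,1.332
Guangdong,2019,1.379
Guangdong,2020,1.484
Guangxi,2016,0.837
Guangxi,2017,0.705
Guangxi,2018,0.892
Guangxi,2019,0.924
Guangxi,2020,1.029
Hainan,2016,0.877
Hainan,2017,0.884
Hainan,2018,0.952
Hainan,2019,0.982
Hainan,2020,1.170
Chongqing,2016,1.169
Chongqing,2017,0.949
Chongqing,2018,1.284
Chongqing,2019,1.340
Chongqing,2020,1.445
Sichuan,2016,0.843
Sichuan,2017,0.689
Sichuan,2018,0.918
Sichuan,2019,0.949
Sichuan,2020,1.015
Guizhou,2016,0.795
Guizhou,2017,0.704
Guizhou,2018,0.897
Guizhou,2019,0.944
Guizhou,2020,1.039
Yunnan,2016,0.566
Yunnan,2017,0.518
Yunnan,2018,0.659
Yunnan,2019,0.707
Yunnan,2020,0.781
Tibet,2016,0.099
Tibet,2017,0.109
Tibet,2018,0.112
Tibet,2019,0.118
Tibet,2020,0.128
Shaanxi,2016,0.917
Shaanxi,2017,0.861
Shaanxi,2018,0.998
Shaanxi,2019,1.038
Shaanxi,2020,1.090
Gansu,2016,0.426
Gansu,2017,0.387
Gansu,2018,0.473
Gansu,2019,0.506
Gansu,2020,0.531
Qinghai,2016,0.177
Qinghai,2017,0.192
Qinghai,2018,0.212
Qinghai,2019,0.214
Qinghai,2020,0.226
Ningxia,2016,0.551
Ningxia,2017,0.622
Ningxia,2018,0.634
Ningxia,2019,0.648
Ningxia,2020,0.699
Xinjiang,2016,0.257
Xinjiang,2017,0.220
Xinjiang,2018,0.260
Xinjiang,2019,0.272
Xinjiang,2020,0.285
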