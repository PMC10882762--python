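province,year,traditional,corrected
Beijing,2016,1.000,0.826
Beijing,2017,1.000,0.840
Beijing,2018,1.000,0.825
Beijing,2019,1.000,0.766
Beijing,2020,1.000,0.750
Tianjin,2016,1.000,0.958
Tianjin,2017,1.000,0.933
Tianjin,2018,1.000,0.895
Tianjin,2019,1.000,0.840
Tianjin,2020,1.000,0.909
Hebei,2016,1.000,0.920
Hebei,2017,1.000,0.938
Hebei,2018,0.992,0.962
Hebei,2019,0.941,0.886
Hebei,2020,0.856,0.808
Shanxi,2016,0.545,0.531
Shanxi,2017,0.534,0.515
Shanxi,2018,0.583,0.561
Shanxi,2019,0.499,0.464
Shanxi,2020,0.493,0.460
Inner Mongolia,2016,0.594,0.577
Inner Mongolia,2017,0.594,0.577
Inner Mongolia,2018,0.610,0.586
Inner Mongolia,2019,0.500,0.465
Inner Mongolia,2020,0.499,0.474
Liaoning,2016,0.641,0.627
Liaoning,2017,0.655,0.638
Liaoning,2018,0.668,0.653
Liaoning,2019,0.637,0.609
Liaoning,2020,0.560,0.543
Jilin,2016,0.489,0.475
Jilin,2017,0.526,0.514
Jilin,2018,0.515,0.501
Jilin,2019,0.491,0.465
Jilin,2020,0.424,0.400
Heilongjiang,2016,0.735,0.717
Heilongjiang,2017,0.714,0.698
Heilongjiang,2018,0.557,0.540
Heilongjiang,2019,0.482,0.456
Heilongjiang,2020,0.416,0.397
Shanghai,2016,1.000,0.837
Shanghai,2017,1.000,0.836
Shanghai,2018,1.000,0.826
Shanghai,2019,1.000,0.765
Shanghai,2020,1.000,0.755
Jiangsu,2016,1.000,0.879
Jiangsu,2017,1.000,0.834
Jiangsu,2018,1.000,0.848
Jiangsu,2019,1.000,0.815
Jiangsu,2020,1.000,0.829
Zhejiang,2016,1.000,0.851
Zhejiang,2017,1.000,0.828
Zhejiang,2018,1.000,0.839
Zhejiang,2019,1.000,0.773
Zhejiang,2020,1.000,0.739
Anhui,2016,1.000,0.945
Anhui,2017,1.000,0.901
Anhui,2018,1.000,0.889
Anhui,2019,1.000,0.776
Anhui,2020,1.000,0.759
Fujian,2016,0.770,0.750
Fujian,2017,0.741,0.719
Fujian,2018,0.766,0.744
Fujian,2019,0.785,0.742
Fujian,2020,0.861,0.818
Jiangxi,2016,1.000,0.907
Jiangxi,2017,1.000,0.872
Jiangxi,2018,1.000,0.878
Jiangxi,2019,1.000,0.853
Jiangxi,2020,1.000,0.896
Shandong,2016,1.000,0.841
Shandong,2017,1.000,0.842
Shandong,2018,1.000,0.834
Shandong,2019,1.000,0.872
Shandong,2020,1.000,0.749
Henan,2016,1.000,0.933
Henan,2017,1.000,0.917
Henan,2018,1.000,0.939
Henan,2019,0.966,0.888
Henan,2020,1.000,0.756
Hubei,2016,1.000,0.870
Hubei,2017,1.000,0.908
Hubei,2018,1.000,0.914
Hubei,2019,1.000,0.893
Hubei,2020,1.000,0.941
Hunan,2016,1.000,0.887
Hunan,2017,1.000,0.907
Hunan,2018,1.000,0.876
Hunan,2019,1.000,0.818
Hunan,2020,1.000,0.824
Guangdong,2016,1.000,0.836
Guangdong,2017,1.000,0.829
Guangdong,2018,1.000,0.834
Guangdong,2019,1.000,0.777
Guangdong,2020,1.000,0.743
Guangxi,2016,1.000,0.942
Guangxi,2017,0.987,0.959
Guangxi,2018,0.993,0.968
Guangxi,2019,1.000,0.902
Guangxi,2020,1.000,0.912
Hainan,2016,0.936,0.899
Hainan,2017,0.906,0.869
Hainan,2018,0.904,0.864
Hainan,2019,0.901,0.834
Hainan,2020,0.929,0.879
Chongqing,2016,1.000,0.904
Chongqing,2017,1.000,0.890
Chongqing,2018,1.000,0.897
Chongqing,2019,1.000,0.869
Chongqing,2020,1.000,0.878
Sichuan,2016,1.000,0.825
Sichuan,2017,1.000,0.827
Sichuan,2018,1.000,0.842
Sichuan,2019,1.000,0.782
Sichuan,2020,1.000,0.748
Guizhou,2016,0.761,0.742
Guizhou,2017,0.744,0.725
Guizhou,2018,0.813,0.794
Guizhou,2019,0.835,0.791
Guizhou,2020,0.729,0.699
Yunnan,2016,1.000,0.939
Yunnan,2017,0.954,0.921
Yunnan,2018,0.969,0.937
Yunnan,2019,1.000,0.924
Yunnan,2020,1.000,0.938
Tibet,2016,1.000,0.895
Tibet,2017,1.000,0.905
Tibet,2018,1.000,0.853
Tibet,2019,1.000,0.784
Tibet,2020,1.000,0.810
Shaanxi,2016,0.727,0.704
Shaanxi,2017,0.774,0.750
Shaanxi,2018,0.771,0.745
Shaanxi,2019,0.748,0.700
Shaanxi,2020,0.654,0.627
Gansu,2016,1.000,0.940
Gansu,2017,1.000,0.922
Gansu,2018,1.000,0.919
Gansu,2019,0.987,0.914
Gansu,2020,1.000,0.933
Qinghai,2016,1.000,0.833
Qinghai,2017,1.000,0.847
Qinghai,2018,1.000,0.842
Qinghai,2019,1.000,0.848
Qinghai,2020,1.000,0.903
Ningxia,2016,1.000,0.848
Ningxia,2017,1.000,0.851
Ningxia,2018,1.000,0.861
Ningxia,2019,1.000,0.823
Ningxia,2020,1.000,0.789
Xinjiang,2016,0.930,0.905
Xinjiang,2017,0.852,0.822
Xinjiang,2018,0.770,0.744
Xinjiang,2019,0.799,0.750
Xinjiang,2020,0.729,0.702
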