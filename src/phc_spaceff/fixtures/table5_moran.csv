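year,moran_i,expected,sd,z,p,p_censored
2016,0.057,-0.033,0.034,2.659,0.004,False
2017,0.050,-0.033,0.034,2.440,0.007,False
2018,0.103,-0.033,0.034,3.983,0.001,True
2019,0.101,-0.033,0.034,3.965,0.001,True
2020,0.125,-0.033,0.034,4.601,0.001,True
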