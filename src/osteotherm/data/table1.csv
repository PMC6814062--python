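sample,experiment,cavity_long_axis_mm,mean_elevation_c,precision_c,energy_kj
1,1,10.0,5.82,0.26,7.87
1,2,10.0,6.22,0.20,7.69
2,3,16.1,6.71,0.41,8.92
2,4,16.1,6.92,0.31,8.59
2,5,16.1,5.91,0.41,10.0
3,6,12.9,6.42,0.23,10.07
4,7,14.1,6.20,0.11,12.17
4,8,14.1,5.69,0.29,10.85
5,9,14.9,6.18,0.18,6.93
5,10,14.9,5.72,0.18,5.74
6,11,10.9,6.30,0.15,10.50
6,12,10.9,5.87,0.20,7.47
6,13,10.9,6.05,0.12,7.79
6,14,10.9,6.32,0.61,8.07
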