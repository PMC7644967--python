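lipid_name,experiment_1,experiment_2,experiment_3
PC 30:1,33.3,57.5,24.3
PC 32:0,66.7,65.8,71.6
PC 32:1,88.9,65.0,67.8
PC 32:2,11.1,65.0,45.9
PC 32:3,66.7,55.0,30.0
PC 32:4,44.4,46.3,23.9
PC 34:0,66.7,15.0,30.2
PC 34:1,100.0,94.9,90.2
PC 34:2,88.9,86.1,60.8
PC 34:3,66.7,88.8,68.5
PC 34:4,77.8,93.7,78.2
PC 36:1,77.8,89.9,74.7
PC 36:2,88.9,88.6,88.4
PC 36:3,66.7,82.2,65.3
PC 36:4,88.9,91.3,86.4
PC 36:5,66.7,78.7,37.2
PC 38:3,88.9,78.8,39.2
PC 38:4,55.6,67.6,44.4
PC 38:5,88.9,77.5,65.5
PC 38:8,44.4,21.3,6.3
PC 40:3,44.4,58.1,36.9
PC 40:4,22.2,33.8,27.7
PC 40:5,22.2,17.5,42.6
PC 40:6,11.1,7.5,58.1
PC 40:9,11.1,5.0,30.0
PE 34:0,28.6,15.0,7.7
PE 34:1,44.4,46.8,30.6
PE 34:2,22.2,16.5,13.3
PE 34:3,11.1,13.9,11.3
PE 36:0,22.2,17.5,8.6
PE 36:1,44.4,32.9,30.9
PE 36:3,11.1,11.4,25.7
PE 36:4,11.1,10.1,7.9
PE 38:6,22.2,15.0,18.6
SM 34:1,33.3,37.7,30.6
SM 36:1,22.2,29.5,18.9
SM 36:2,22.2,37.5,7.9
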