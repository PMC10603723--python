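temperature,weight_class,e_g,determined
10,30,33.70,1
10,50,35.01,1
10,70,33.56,1
10,90,31.29,1
10,110,29.06,0
10,130,26.93,0
10,150,25.15,1
10,170,24.02,0
14,30,20.52,0
14,50,22.06,0
14,70,20.25,0
14,90,19.33,0
14,110,18.01,0
14,130,17.40,0
14,150,14.98,0
14,170,14.11,0
18,30,14.2,1
18,50,16.03,1
18,70,14.11,1
18,90,12.97,0
18,110,12.31,1
18,130,12.19,1
18,150,9.72,1
18,170,8.97,1
22,30,19.48,0
22,50,21.50,0
22,70,19.12,0
22,90,15.92,0
22,110,14.29,0
22,130,14.14,0
22,150,12.61,0
22,170,11.69,0
26,30,31.8,0
26,50,34.22,1
26,70,31.76,1
26,90,24.33,1
26,110,21.50,0
26,130,20.23,1
26,150,20.44,0
26,170,19.21,1
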