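temperature,weight_class,e_g
10,30,33.70
10,50,35.01
10,70,33.56
10,90,31.29
10,150,25.15
18,30,14.2
18,50,16.03
18,70,14.11
18,110,12.31
18,130,12.19
18,150,9.72
18,170,8.97
26,50,34.22
26,70,31.76
26,90,24.33
26,130,20.23
26,170,19.21
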