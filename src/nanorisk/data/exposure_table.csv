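mt,we,mean_ug_m3,sd_ug_m3
MT1,WE1,0.83,0.18
MT1,WE2,1.0,0.07
MT1,WE3,1.2,0.12
MT1,WH,1.2,0.32
MT1,NWH,0.92,0.31
MT2,WE1,3.4,22
MT2,WE2,25,3.80
MT2,WE3,6.1,12.0
MT2,WH,6.7,22.0
MT2,NWH,4.5,6
MT3,WE1,0.81,0.82
MT3,WE2,1.7,0.69
MT3,WE3,NA,NA
MT3,WH,1.5,5.7
MT3,NWH,0.42,0.21
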