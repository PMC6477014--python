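volunteer,day,duration_min,interval_min,observations,liquid_ml,urine_ml,ref_volume_ml,samples_acquired
V1,1,163,15,8,350,215,240,304
V1,2,157,15,7,500,225,240,270
V1,3,142,15,8,500,235,240,310
V1,4,168,30,4,500,255,240,284
V1,5,170,30,5,500,230,240,310
V2,1,155,15,9,500,330,330,330
V2,2,178,15,8,500,335,330,314
V2,3,160,15,8,400,310,330,340
V2,4,155,30,5,500,330,330,324
V2,5,164,30,6,300,315,330,304
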