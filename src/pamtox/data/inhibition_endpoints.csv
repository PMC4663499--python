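herbicide,duration_h,ic10,ic10_lo,ic10_hi,ic50,ic50_lo,ic50_hi,r2,rep_reported
diuron,24,1.2,1.0,1.5,4.3,3.9,4.7,0.99,1.0
fluometuron,24,17,13,22,132,116,150,0.99,0.033
tebuthiuron,24,3.9,2.9,5.2,28,24,31,0.98,0.16
atrazine,24,3.4,2.8,4.0,22,20,24,0.99,0.19
ametryn,24,1.4,1.1,1.8,5.6,4.9,6.3,0.99,0.77
metribuzin,24,1.9,1.6,2.3,7.0,6.5,7.5,0.99,0.61
simazine,24,3.0,2.5,3.6,28,26,30,0.99,0.15
prometryn,24,3.7,2.8,4.9,11,9.4,12,0.99,0.41
bromacil,24,3.4,2.6,4.6,25,22,29,0.99,0.17
hexazinone,24,6.4,5.6,7.3,17,16,18,0.99,0.26
ametryn,48,0.8,0.6,1.0,3.5,3.0,4.0,0.99,1.23
metribuzin,48,0.8,0.6,1.0,4.8,4.3,5.3,0.99,0.90
prometryn,48,1.6,1.3,2.0,6.7,6.0,7.5,0.99,0.64
hexazinone,48,2.5,2.0,3.0,11,9.7,12,0.99,0.41
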