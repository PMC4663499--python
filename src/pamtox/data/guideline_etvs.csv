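herbicide,source,protection_pct,etv_ugL,reported_nonprotective
diuron,anzecc_current,99,1.8,1
diuron,anzecc_current,95,1.8,1
diuron,anzecc_current,90,1.8,1
diuron,anzecc_proposed,99,0.08,0
diuron,anzecc_proposed,95,0.3,0
diuron,anzecc_proposed,90,0.4,0
diuron,gbrmpa,99,0.9,0
diuron,gbrmpa,95,1.6,1
diuron,gbrmpa,90,2.3,1
fluometuron,anzecc_current,99,,
fluometuron,anzecc_current,95,,
fluometuron,anzecc_current,90,,
fluometuron,anzecc_proposed,99,,
fluometuron,anzecc_proposed,95,,
fluometuron,anzecc_proposed,90,,
fluometuron,gbrmpa,99,,
fluometuron,gbrmpa,95,,
fluometuron,gbrmpa,90,,
tebuthiuron,anzecc_current,99,0.02,0
tebuthiuron,anzecc_current,95,2.2,0
tebuthiuron,anzecc_current,90,20,1
tebuthiuron,anzecc_proposed,99,4.3,1
tebuthiuron,anzecc_proposed,95,8.8,1
tebuthiuron,anzecc_proposed,90,12.0,1
tebuthiuron,gbrmpa,99,0.02,0
tebuthiuron,gbrmpa,95,2,0
tebuthiuron,gbrmpa,90,20,0
atrazine,anzecc_current,99,0.7,0
atrazine,anzecc_current,95,13,1
atrazine,anzecc_current,90,45,1
atrazine,anzecc_proposed,99,2.8,0
atrazine,anzecc_proposed,95,3.8,1
atrazine,anzecc_proposed,90,4.6,1
atrazine,gbrmpa,99,0.6,0
atrazine,gbrmpa,95,1.4,0
atrazine,gbrmpa,90,2.5,0
ametryn,anzecc_current,99,,
ametryn,anzecc_current,95,,
ametryn,anzecc_current,90,,
ametryn,anzecc_proposed,99,0.02,0
ametryn,anzecc_proposed,95,0.1,0
ametryn,anzecc_proposed,90,0.3,0
ametryn,gbrmpa,99,0.5,0
ametryn,gbrmpa,95,1.0,1
ametryn,gbrmpa,90,1.6,1
metribuzin,anzecc_current,99,,
metribuzin,anzecc_current,95,,
metribuzin,anzecc_current,90,,
metribuzin,anzecc_proposed,99,,
metribuzin,anzecc_proposed,95,,
metribuzin,anzecc_proposed,90,,
metribuzin,gbrmpa,99,,
metribuzin,gbrmpa,95,,
metribuzin,gbrmpa,90,,
simazine,anzecc_current,99,,
simazine,anzecc_current,95,,
simazine,anzecc_current,90,,
simazine,anzecc_proposed,99,,
simazine,anzecc_proposed,95,,
simazine,anzecc_proposed,90,,
simazine,gbrmpa,99,0.2,0
simazine,gbrmpa,95,3.2,0
simazine,gbrmpa,90,11,0
prometryn,anzecc_current,99,,
prometryn,anzecc_current,95,,
prometryn,anzecc_current,90,,
prometryn,anzecc_proposed,99,,
prometryn,anzecc_proposed,95,,
prometryn,anzecc_proposed,90,,
prometryn,gbrmpa,99,,
prometryn,gbrmpa,95,,
prometryn,gbrmpa,90,,
bromacil,anzecc_current,99,,
bromacil,anzecc_current,95,,
bromacil,anzecc_current,90,,
bromacil,anzecc_proposed,99,,
bromacil,anzecc_proposed,95,,
bromacil,anzecc_proposed,90,,
bromacil,gbrmpa,99,,
bromacil,gbrmpa,95,,
bromacil,gbrmpa,90,,
hexazinone,anzecc_current,99,75,1
hexazinone,anzecc_current,95,75,1
hexazinone,anzecc_current,90,75,1
hexazinone,anzecc_proposed,99,0.9,0
hexazinone,anzecc_proposed,95,1.2,0
hexazinone,anzecc_proposed,90,1.5,0
hexazinone,gbrmpa,99,1.2,0
hexazinone,gbrmpa,95,1.2,0
hexazinone,gbrmpa,90,1.2,0
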