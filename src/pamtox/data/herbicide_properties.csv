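herbicide,chemical_class,log_kow,water_solubility_mgL,cas_number
diuron,phenylurea,2.6,37.4,330-54-1
fluometuron,phenylurea,2.4,110,2164-17-2
tebuthiuron,phenylurea,1.8,2500,34014-18-1
atrazine,s-triazine,2.5,29800,1912-24-9
ametryn,s-triazine,2.6,200,834-12-8
metribuzin,s-triazine,1.6,1050,21087-64-9
simazine,s-triazine,2.1,6.2,122-34-9
prometryn,s-triazine,3.1,33,7287-19-6
bromacil,uracil,1.9,807,317-40-9
hexazinone,triazinone,1.2,33000,51235-04-2
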