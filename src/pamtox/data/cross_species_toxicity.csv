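herbicide,duration,test_phylum,common_name,endpoint,response_concentration,reference
diuron,24 h,Angiospermae,Seagrass,dF/Fm' (IC50),4.3 ug/l,present study
diuron,24 h,Angiospermae,Seagrass,dF/Fm' (IC50),3.5 ug/l,ref 8
diuron,72 h,Angiospermae,Seagrass,dF/Fm'/Fv/Fm,2.4-2.47 ug/l,ref 12
diuron,5 day,Angiospermae,Seagrass,dF/Fm' (LOEC),0.1 ug/l,ref 65
diuron,4 days,Angiospermae,Seagrass,dF/Fm' (LOEC),10 ug/l,ref 49
diuron,77 days,Angiospermae,Seagrass,dF/Fm' (IC50),2.4-2.8 ug/l,ref 13
diuron,34 h,Dinoflagellate,Coral,dF/Fm' (IC50),2.9-5.9 ug/l,ref 51
diuron,2-3 mo,Dinoflagellate,Coral,dF/Fm' (IC50),1.2-5.0 ug/l,ref 66
diuron,4 day,Heterokontophceae,Diatom,dF/Fm' (IC50),2.6-18 ug/l,ref 23
diuron,4 day,Chlorophyceae,Green algae,dF/Fm' (IC50),2.1 ug/l,ref 23
fluometuron,24 h,Angiospermae,Seagrass,dF/Fm' (IC50),132 ug/l,present study
fluometuron,30 min + 48 h,Chlorophyceae,Green algae,Growth,2.5-10 ml/l,ref 67
tebuthiuron,24 h,Angiospermae,Seagrass,dF/Fm' (IC50),28 ug/l,present study
tebuthiuron,72 h,Angiospermae,Seagrass,dF/Fm' (IC50),29.1-29.7 ug/l,ref 12
tebuthiuron,24 h,Dinoflagellate,Coral,dF/Fm' (IC50),175 ug/l,ref 68
tebuthiuron,4 day,Heterokontophceae,Diatom,dF/Fm' (IC50),51-94 ug/l,ref 23
tebuthiuron,4 day,Chlorophyceae,Green algae,dF/Fm' (IC50),12 ug/l,ref 23
atrazine,24 h,Angiospermae,Seagrass,dF/Fm' (IC50),22 ug/l,present study
atrazine,72 h,Angiospermae,Seagrass,dF/Fm' (IC50),13.4-18.2 ug/l,ref 12
atrazine,96 h,Angiospermae,Seagrass,dF/Fm' (LOEC),10 ug/l,ref 49
atrazine,14 d,Angiospermae,Aquatic plants,dF/Fm' (IC50),22-132 ug/l,ref 50
atrazine,96 h,Chlorophyceae,Green algae,dF/Fm' (IC50),94-176 ug/l,ref 50
atrazine,24 h,Chlorophyceae,Green algae,dF/Fm' (IC50),38.8 ug/l,ref 45
atrazine,2 h,Chlorophyceae,Green algae,dF/Fm' (IC50),103 ug/l,ref 52
atrazine,2 h,Heterokontophceae,Diatom,dF/Fm' (IC50),45 ug/l,ref 52
atrazine,24 h,Dinoflagellate,Coral,dF/Fm' (IC50),45 ug/l,ref 68
atrazine,34 h,Dinoflagellate,Coral,dF/Fm' (IC50),37-88.2 ug/l,ref 51
atrazine,4 day,Heterokontophceae,Diatom,dF/Fm' (IC50),34-77 ug/l,ref 23
atrazine,4 day,Chlorophyceae,Green algae,dF/Fm' (IC50),14 ug/l,ref 23
ametryn,48 h,Angiospermae,Seagrass,dF/Fm' (IC50),3.6 ug/l,present study
ametryn,24 h,Chlorophyceae,Green algae,dF/Fm' (IC50),3.6 ug/l,ref 45
ametryn,24 h,Dinoflagellate,Coral,dF/Fm' (IC50),1.7 ug/l,ref 68
metribuzin,48 h,Angiospermae,Seagrass,dF/Fm' (IC50),4.8 ug/l,present study
metribuzin,14 d,Angiospermae,Aquatic plants,dF/Fm' (IC50),14-36 ug/l,ref 50
metribuzin,h - days,Chlorophyceae,Green algae,dF/Fm' (IC50),12.3-39.7 ug/l,ref 69
metribuzin,96 h,Chlorophyceae,Green algae,dF/Fm' (IC50),23-152 ug/l,ref 50
simazine,24 h,Angiospermae,Seagrass,dF/Fm' (IC50),28 ug/l,present study
simazine,96 h,Angiospermae,Seagrass,dF/Fm' (LOEC),10 ug/l,ref 49
simazine,24 h,Chlorophyceae,Green algae,dF/Fm' (IC50),56.9 ug/l,ref 45
simazine,24 h,Dinoflagellate,Coral,dF/Fm' (IC50),150 ug/l,ref 68
simazine,2 h,Chlorophyceae,Green algae,dF/Fm' (IC50),76 ug/l,ref 52
simazine,2 h,Heterokontophceae,Diatom,dF/Fm' (IC50),400 ug/l,ref 52
prometryn,48 h,Angiospermae,Seagrass,dF/Fm' (IC50),6.7 ug/l,present study
prometryn,24 h,Chlorophyceae,Green algae,dF/Fm'/Fv/Fm,13.2 ug/l,ref 45
bromacil,24 h,Angiospermae,Seagrass,dF/Fm' (IC50),25 ug/l,present study
bromacil,2 h,Phaeophyceae,Macroalgae,dF/Fm' (IC50),8.23 ug/l,ref 70
hexazinone,48 h,Angiospermae,Seagrass,dF/Fm' (IC50),11 ug/l,present study
hexazinone,72 h,Angiospermae,Seagrass,dF/Fm'/Fv/Fm,4.4-6.9 ug/l,ref 12
hexazinone,24 h,Dinoflagellate,Coral,dF/Fm'/Fv/Fm,8.8 ug/l,ref 68
hexazinone,2 h,Chlorophyceae,Green algae,dF/Fm'/Fv/Fm,21 ug/l,ref 52
hexazinone,2 h,Heterokontophceae,Diatom,dF/Fm' (IC50),22 ug/l,ref 52
hexazinone,4 day,Heterokontophceae,Diatom,dF/Fm' (IC50),5.7-6.9 ug/l,ref 23
hexazinone,4 day,Chlorophyceae,Green algae,dF/Fm' (IC50),2.4 ug/l,ref 23
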