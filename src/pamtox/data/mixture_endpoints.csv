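mixture_id,ic10_tu,ic10_lo,ic10_hi,ic50_tu,ic50_lo,ic50_hi,group_letters
diuron+diuron,0.23,0.20,0.27,0.90,0.87,0.94,ab
atrazine+atrazine,0.17,0.14,0.20,0.95,0.90,1.0,a
diuron+atrazine,0.15,0.12,0.18,0.85,0.81,0.90,b
10-herbicide-mix,0.17,0.14,0.20,0.87,0.8,0.95,ab
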