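sample_id,group,organ,analyte,delta13C,replicate
diet_01,DIET,none,Ile,-23.4804,1
diet_01,DIET,none,Ile,-23.2687,2
diet_01,DIET,none,Leu,-28.1238,1
diet_01,DIET,none,Leu,-27.8843,2
diet_01,DIET,none,Lys,-21.4350,1
diet_01,DIET,none,Lys,-21.4026,2
diet_01,DIET,none,Phe,-27.7134,1
diet_01,DIET,none,Phe,-27.7988,2
diet_01,DIET,none,Thr,-17.8591,1
diet_01,DIET,none,Thr,-17.5310,2
diet_01,DIET,none,Val,-25.3561,1
diet_01,DIET,none,Val,-25.2031,2
diet_02,DIET,none,Ile,-23.7790,1
diet_02,DIET,none,Ile,-23.7537,2
diet_02,DIET,none,Leu,-28.0975,1
diet_02,DIET,none,Leu,-27.7354,2
diet_02,DIET,none,Lys,-21.3259,1
diet_02,DIET,none,Lys,-21.5943,2
diet_02,DIET,none,Phe,-27.3122,1
diet_02,DIET,none,Phe,-27.7667,2
diet_02,DIET,none,Thr,-17.7897,1
diet_02,DIET,none,Thr,-17.5615,2
diet_02,DIET,none,Val,-25.4313,1
diet_02,DIET,none,Val,-25.4869,2
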