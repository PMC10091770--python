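name,parent_stage,start_ma,end_ma
Zlichovian,Emsian,407.6,400.5
Dalejan,Emsian,400.5,393.3
Early Famennian,Famennian,372.2,365.0
Late Famennian,Famennian,365.0,358.9
Chadian,Visean,346.7,343.0
Arundian,Visean,343.0,339.4
Holkerian,Visean,339.4,336.8
Asbian,Visean,336.8,333.0
Brigantian,Visean,333.0,330.9
Pendleian,Serpukhovian,330.9,327.5
Arnsbergian,Serpukhovian,327.5,323.2
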