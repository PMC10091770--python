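name,period,start_ma,end_ma
Lochkovian,Devonian,419.2,410.8
Pragian,Devonian,410.8,407.6
Emsian,Devonian,407.6,393.3
Eifelian,Devonian,393.3,387.7
Givetian,Devonian,387.7,382.7
Frasnian,Devonian,382.7,372.2
Famennian,Devonian,372.2,358.9
Tournaisian,Carboniferous,358.9,346.7
Visean,Carboniferous,346.7,330.9
Serpukhovian,Carboniferous,330.9,323.2
Bashkirian,Carboniferous,323.2,315.2
Moscovian,Carboniferous,315.2,307.0
Kasimovian,Carboniferous,307.0,303.7
Gzhelian,Carboniferous,303.7,298.9
Asselian,Permian,298.9,293.52
Sakmarian,Permian,293.52,290.1
Artinskian,Permian,290.1,283.5
Kungurian,Permian,283.5,273.01
Roadian,Permian,273.01,266.9
Wordian,Permian,266.9,264.28
Capitanian,Permian,264.28,259.51
Wuchiapingian,Permian,259.51,254.14
Changhsingian,Permian,254.14,251.902
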