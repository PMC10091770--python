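composite_id,label,member_kind,member_name
EL01,Lochkovian-Pragian,stage,Lochkovian
EL01,Lochkovian-Pragian,stage,Pragian
EL02,early Emsian (Zlichovian),substage,Zlichovian
EL03,late Emsian (Dalejan),substage,Dalejan
EL04,Eifelian-Givetian,stage,Eifelian
EL04,Eifelian-Givetian,stage,Givetian
EL05,Frasnian,stage,Frasnian
EL06,early Famennian,substage,Early Famennian
EL07,late Famennian,substage,Late Famennian
EL08,Tournaisian,stage,Tournaisian
EL09,early Visean (Chadian-Holkerian),substage,Chadian
EL09,early Visean (Chadian-Holkerian),substage,Arundian
EL09,early Visean (Chadian-Holkerian),substage,Holkerian
EL10,late Visean (Asbian-Brigantian),substage,Asbian
EL10,late Visean (Asbian-Brigantian),substage,Brigantian
EL11,Serpukhovian,stage,Serpukhovian
EL12,Bashkirian,stage,Bashkirian
EL13,Moscovian,stage,Moscovian
EL14,Kasimovian-Gzhelian,stage,Kasimovian
EL14,Kasimovian-Gzhelian,stage,Gzhelian
EL15,Asselian-Sakmarian,stage,Asselian
EL15,Asselian-Sakmarian,stage,Sakmarian
EL16,Artinskian,stage,Artinskian
EL17,Kungurian,stage,Kungurian
EL18,Roadian,stage,Roadian
EL19,Wordian-Capitanian,stage,Wordian
EL19,Wordian-Capitanian,stage,Capitanian
EL20,Lopingian,stage,Wuchiapingian
EL20,Lopingian,stage,Changhsingian
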