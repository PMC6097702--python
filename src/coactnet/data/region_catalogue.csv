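abbreviation,full_name,system,in_dorsal_hippocampus
LADL,Lateral amygdala dorsolateral part,amygdalar,False
LAVL,Lateral amygdala ventrolateral part,amygdalar,False
LAVM,Lateral amygdala ventromedial part,amygdalar,False
BLA,Basolateral amygdala anterior part,amygdalar,False
BLP,Basolateral amygdala posterior part,amygdalar,False
BLV,Basolateral amygdala ventral part,amygdalar,False
CeC,Central amygdala capsular part,amygdalar,False
CeL,Central amygdala lateral part,amygdalar,False
CeM,Central amygdala medial part,amygdalar,False
dCA1,Dorsal CA1,dorsal-hippocampal,True
dCA3,Dorsal CA3,dorsal-hippocampal,True
dDG,Dorsal dentate gyrus,dorsal-hippocampal,True
vCA1,Ventral CA1,ventral-hippocampal,False
vCA3,Ventral CA3,ventral-hippocampal,False
vDG,Ventral dentate gyrus,ventral-hippocampal,False
vSub,Ventral subiculum,ventral-hippocampal,False
Per_36,Perirhinal cortex area 36,parahippocampal,False
Per_35,Perirhinal cortex area 35,parahippocampal,False
Por,Postrhinal cortex,parahippocampal,False
DLE,Dorsolateral entorhinal cortex,parahippocampal,False
DIE,Dorsal intermediate entorhinal cortex,parahippocampal,False
MEnt,Medial entorhinal cortex,parahippocampal,False
PrL,Prelimbic cortex,prefrontal,False
IL,Infralimbic cortex,prefrontal,False
Cg1,Cingulate cortex area 1,prefrontal,False
Cg2,Cingulate cortex area 2,prefrontal,False
MO,Medial orbital cortex,prefrontal,False
RSC,Retrosplenial disgranular cortex,retrosplenial,False
RSGd,Retrosplenial granular cortex dorsal,retrosplenial,False
RSGv,Retrosplenial granular cortex ventral,retrosplenial,False
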