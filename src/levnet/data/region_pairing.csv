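unilateral,bilateral,full_name
AI_L,AI,agranular insular cortex
AI_R,AI,agranular insular cortex
AuDMV_L,AuDMV,auditory cortex (dorsal/medial/ventral)
AuDMV_R,AuDMV,auditory cortex (dorsal/medial/ventral)
CC_L,CC,corpus callosum
CC_R,CC,corpus callosum
Cg_L,Cg,cingulate cortex
Cg_R,Cg,cingulate cortex
CPu_L,CPu,caudate putamen
CPu_R,CPu,caudate putamen
DI_L,DI,dysgranular insular cortex
DI_R,DI,dysgranular insular cortex
DLIVEnt_L,DLIVEnt,entorhinal cortex (dorsolateral/intermediate/ventral)
DLIVEnt_R,DLIVEnt,entorhinal cortex (dorsolateral/intermediate/ventral)
DLO_L,DLO,dorsolateral orbital cortex
DLO_R,DLO,dorsolateral orbital cortex
ECT_L,ECT,ectorhinal cortex
ECT_R,ECT,ectorhinal cortex
Fornix_L,Fornix,fornix
Fornix_R,Fornix,fornix
FrA_L,FrA,frontal association cortex
FrA_R,FrA,frontal association cortex
HIP_L,HIP,hippocampus
HIP_R,HIP,hippocampus
LO_L,LO,lateral orbital cortex
LO_R,LO,lateral orbital cortex
M1_L,M1,primary motor cortex
M1_R,M1,primary motor cortex
M2_L,M2,secondary motor cortex
M2_R,M2,secondary motor cortex
MO_L,MO,medial orbital cortex
MO_R,MO,medial orbital cortex
PRH_L,PRH,perirhinal cortex
PRH_R,PRH,perirhinal cortex
PrL_L,PrL,prelimbic cortex
PrL_R,PrL,prelimbic cortex
PtA_L,PtA,parietal association cortex
PtA_R,PtA,parietal association cortex
PtPR_L,PtPR,posterior parietal cortex (rostral)
PtPR_R,PtPR,posterior parietal cortex (rostral)
RSC_L,RSC,retrosplenial cortex
RSC_R,RSC,retrosplenial cortex
S1_L,S1,primary somatosensory cortex
S1_R,S1,primary somatosensory cortex
S2_L,S2,secondary somatosensory cortex
S2_R,S2,secondary somatosensory cortex
TeA_L,TeA,temporal association cortex
TeA_R,TeA,temporal association cortex
TH_L,TH,thalamus
TH_R,TH,thalamus
V1V2_L,V1V2,visual cortex (primary/secondary)
V1V2_R,V1V2,visual cortex (primary/secondary)
VO_L,VO,ventral orbital cortex
VO_R,VO,ventral orbital cortex
Cerebellum_L,Cerebellum,cerebellum
Cerebellum_R,Cerebellum,cerebellum
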