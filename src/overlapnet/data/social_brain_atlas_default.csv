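name,hemisphere,x,y,z,cluster
FG_L,left,-42,-50,-20,visual_sensory
FG_R,right,42,-50,-20,visual_sensory
MTV5_L,left,-46,-68,4,visual_sensory
MTV5_R,right,46,-68,4,visual_sensory
pSTS_L,left,-52,-40,6,visual_sensory
pSTS_R,right,52,-40,6,visual_sensory
AM_L,left,-22,-4,-18,limbic
AM_R,right,22,-4,-18,limbic
HC_L,left,-26,-22,-14,limbic
HC_R,right,26,-22,-14,limbic
NAC_L,left,-10,10,-8,limbic
NAC_R,right,10,10,-8,limbic
rACC,midline,0,38,8,limbic
vmPFC,midline,0,46,-14,limbic
AI_L,left,-36,18,2,intermediate
AI_R,right,36,18,2,intermediate
aMCC,midline,0,22,34,intermediate
CB_L,left,-24,-76,-34,intermediate
CB_R,right,24,-76,-34,intermediate
IFG_L,left,-48,26,6,intermediate
IFG_R,right,48,26,6,intermediate
SMA_L,left,-6,8,58,intermediate
SMA_R,right,6,8,58,intermediate
SMG_L,left,-58,-34,34,intermediate
SMG_R,right,58,-34,34,intermediate
dmPFC,midline,0,54,24,higher_associative
FP,midline,0,60,-4,higher_associative
MTG_L,left,-56,-16,-12,higher_associative
MTG_R,right,56,-16,-12,higher_associative
PCC,midline,0,-50,26,higher_associative
pMCC,midline,0,-16,40,higher_associative
PREC,midline,0,-60,40,higher_associative
TP_L,left,-44,14,-32,higher_associative
TP_R,right,44,14,-32,higher_associative
TPJ_L,left,-52,-54,24,higher_associative
TPJ_R,right,52,-54,24,higher_associative
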