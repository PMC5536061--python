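name,size,source,accession
CACO2_DIFF_VS_UNDIFF,579,"Pellis et al., 2005",GSE2047
CACO2_DIFF_VS_HT29MTX,1371,"-2 < FcLOG < 2",GSE30292
CACO2_DIFF_VS_ENTERO,6038,"-2 < FcLOG < 2",GSE30292
COLONOCYTE,103,COPE (PubMed list),
ENTEROCYTE,142,COPE (PubMed list),
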