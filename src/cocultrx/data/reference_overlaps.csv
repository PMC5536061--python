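name_a,name_b,common,printed_pct_a,printed_pct_b,printed_discrepancy
CACO2_DIFF_VS_UNDIFF,CACO2_DIFF_VS_HT29MTX,79,13.6,5.8,
CACO2_DIFF_VS_UNDIFF,CACO2_DIFF_VS_ENTERO,296,51.1,4.9,
CACO2_DIFF_VS_UNDIFF,COLONOCYTE,11,1.9,10.7,
CACO2_DIFF_VS_UNDIFF,ENTEROCYTE,12,2.1,8.5,
CACO2_DIFF_VS_HT29MTX,CACO2_DIFF_VS_ENTERO,846,61.7,14.0,
CACO2_DIFF_VS_HT29MTX,COLONOCYTE,12,0.9,11.7,
CACO2_DIFF_VS_HT29MTX,ENTEROCYTE,13,0.9,9.2,
CACO2_DIFF_VS_ENTERO,COLONOCYTE,22,0.4,21.4,
CACO2_DIFF_VS_ENTERO,ENTEROCYTE,28,0.4,19.7,pct_a
COLONOCYTE,ENTEROCYTE,50,48.5,35.2,
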