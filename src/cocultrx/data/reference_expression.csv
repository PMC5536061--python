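gene,group,caco2_mean,caco2_sd,ht29mtx_mean,ht29mtx_sd,coculture_mean,coculture_sd,printed_fc_theoric,fc_oa_mean,fc_oa_sd,fc_oa_call
ATOH1,intestinal_phenotype,1366,30,17481,1590,212,29,-14,3.4,0.2,up
GFI1,intestinal_phenotype,4.20,0.10,56.0,9.4,0.7,0.1,-14,3.9,0.1,up
HES1,intestinal_phenotype,1260,338,1697,36,527,29,-2,1.6,0.1,up
MUC2,intestinal_phenotype,17.4,1.6,1.4,0.2,2.0,0.5,-8,2.4,1.7,up
MUC5AC,intestinal_phenotype,1540,10,30661,1314,619,27,-7,4.2,0.0,up
SOX9,intestinal_phenotype,228,10,489,83,158,20,-2,-3.2,0.0,down
TFF3,intestinal_phenotype,580774,2,485507,15791,101000,882,-6,4.3,0.2,up
FAT_CD36,fatty_acid_uptake,0.05,0.03,1.32,0.35,0.05,0.00,-3,1.0,0.1,unchanged
FABP1,fatty_acid_uptake,263971,115167,27,2,50176,4078,-5,4.9,0.4,up
FABP3,fatty_acid_uptake,191,18,3.2,0.5,98,8,-2,2.0,0.5,up
FABP4,fatty_acid_uptake,4.05,0.62,0.69,0.14,0.15,0.03,-25,26.7,8.3,up
GPR120,fatty_acid_uptake,2844,91,9007,473,312,8,-11,5.4,0.2,up
ABDH5,lipid_droplet,507,158,165,14,184,28,-3,3.7,1.5,up
PLIN1,lipid_droplet,,,0.03,0.004,0.002,0.001,,-1.6,0.1,unchanged
PLIN2,lipid_droplet,,,,,,,,,,
PLIN3,lipid_droplet,3199,870,1670,63,1200,271,-3,2.7,0.1,up
PLIN5,lipid_droplet,0.005,0.001,0.031,0.008,0.001,0.000,-10,1.9,0.1,up
CIDEA,lipid_droplet,,,,,,,,,,
CIDEB,lipid_droplet,16.1,2.8,18.1,2.0,3.1,0.1,-5,3.2,0.2,up
CIDEC,lipid_droplet,16762,2219,4837,64,2217,49,-7,2.3,0.2,up
XBP1,upr_stress,19033,634,61810,2713,13454,6654,-2,-1.4,0.0,unchanged
TSPAN8,cancer_marker,124836,3825,706666,5070,19088,3500,-10,4.7,0.0,up
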