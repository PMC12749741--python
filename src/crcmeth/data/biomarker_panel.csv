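gene,probe_id,region_group,specimen
ADHFE1,cg18065361,TSS200,stool
BCAT1,cg02765913,5UTR,plasma
BMP3,cg20276585,TSS200,plasma
C9orf50,cg18973112,TSS200,stool
CLIP4,cg09695033,TSS1500,stool
CNRIP1,cg11573679,1stExon,stool
COL25A1,cg07095995,TSS200,plasma
FBN1,cg15385562,TSS1500,stool
FNB1,cg15385562,TSS1500,stool
FOXF1,cg00314966,1stExon,plasma
GATA5,cg16714055,TSS1500,plasma
GRIA4,cg04747226,TSS200,stool
HAND1,cg03158581,TSS1500,plasma
IKZF1,cg23140175,TSS200,plasma
KCNJ12,cg27056599,TSS200,plasma
KCNQ5,cg09303936,TSS1500,stool
LIFR,cg11841722,TSS1500,plasma
LINC00473,cg09830769,TSS1500,plasma
MAL,cg04804539,TSS1500,stool
METAP1D,cg08750504,3UTR,plasma
MPPED2,cg11855526,5UTR,plasma
NDRG4,cg00687686,TSS1500,stool
NPY,cg00355281,TSS200,plasma
PPP2R5C,cg00723271,Body,stool
SDC2,cg24732574,TSS200,stool
SEPT9,cg17300544,TSS200,plasma
SHOX2,cg06759819,Body,plasma
SNCA,cg08767460,TSS1500,stool
SPG20,cg03966514,5UTR,stool
TFPI2,cg15649801,TSS1500,stool
TWIST1,cg09799658,TSS200,plasma
VIPR2,cg03976877,1stExon,stool
WIF1,cg26733786,5UTR,plasma
ZNF132,cg03735888,TSS200,plasma
ZNF304,cg21627760,TSS200,plasma
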