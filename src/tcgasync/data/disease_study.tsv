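code	name
BRCA	Breast invasive carcinoma
GBM	Glioblastoma multiforme
OV	Ovarian serous cystadenocarcinoma
LUAD	Lung adenocarcinoma
COAD	Colon adenocarcinoma
KIRC	Kidney renal clear cell carcinoma
PRAD	Prostate adenocarcinoma
STAD	Stomach adenocarcinoma
LGG	Brain lower grade glioma
SKCM	Skin cutaneous melanoma
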