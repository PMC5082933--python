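code	name
01	Primary Solid Tumor
02	Recurrent Solid Tumor
03	Primary Blood Derived Cancer
06	Metastatic
10	Blood Derived Normal
11	Solid Tissue Normal
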