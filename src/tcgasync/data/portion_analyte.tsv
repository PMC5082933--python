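code	name
D	DNA
G	Whole Genome Amplified DNA
H	mirVana RNA
R	RNA
T	Total RNA
W	Whole Genome Amplified DNA (Qiagen)
X	Whole Genome Amplified DNA (second reaction)
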