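code	name
A1	Albert Einstein Medical Center
A2	Walter Reed National Military Medical Center
A7	Christiana Healthcare
BH	University of Pittsburgh
E2	Roswell Park Cancer Institute
02	MD Anderson Cancer Center
06	Henry Ford Hospital
09	University of California San Francisco
13	Memorial Sloan Kettering Cancer Center
CH	Indiana University
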