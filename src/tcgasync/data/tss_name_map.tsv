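raw_name	canonical_name
Univ. of Pittsburgh	University of Pittsburgh
University of  Pittsburgh	University of Pittsburgh
University-of-Pittsburgh	University of Pittsburgh
Univeristy of Pittsburgh	University of Pittsburgh
MD Anderson	MD Anderson Cancer Center
M.D. Anderson Cancer Center	MD Anderson Cancer Center
MD Anderson-Cancer Center	MD Anderson Cancer Center
Memorial Sloan-Kettering Cancer Center	Memorial Sloan Kettering Cancer Center
MSKCC	Memorial Sloan Kettering Cancer Center
Roswell Park	Roswell Park Cancer Institute
Roswell  Park Cancer Institute	Roswell Park Cancer Institute
UCSF	University of California San Francisco
Walter Reed	Walter Reed National Military Medical Center
Christiana Health Care	Christiana Healthcare
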