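code	name
01	broad.mit.edu
02	hms.harvard.edu
03	lbl.gov
04	mskcc.org
05	jhu-usc.edu
07	unc.edu
08	mdanderson.org
09	genome.wustl.edu
10	bcgsc.ca
13	bcm.edu
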