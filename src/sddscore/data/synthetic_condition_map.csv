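code,category
SYN-SLD-1,SLD
SYN-SLD-2,SLD
SYN-MASH-1,MASH
SYN-MASH-2,MASH
SYN-ALD-1,ALD
SYN-ALD-2,ALD
SYN-CIRR-1,cirrhosis
SYN-CIRR-2,cirrhosis
SYN-HCC-1,HCC
SYN-HCC-2,HCC
SYN-HBV-1,chronic_HBV
SYN-HBV-2,chronic_HBV
SYN-HCV-1,chronic_HCV
SYN-HCV-2,chronic_HCV
SYN-HF-1,hepatic_failure
SYN-HF-2,hepatic_failure
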