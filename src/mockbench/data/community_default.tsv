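name	copy_number	cell_fraction
Escherichia coli ATCC 47076	7	1
Staphylococcus aureus ATCC 12600	6	1
Pseudomonas aeruginosa ATCC 10145	4	1
Streptococcus agalactiae ATCC 12403	7	1
Corynebacterium tuberculostearicum ATCC 35692	8	1
Enterococcus faecalis ATCC 19433	4	1
Lactobacillus iners DSMZ 13335	5	1
Lactobacillus crispatus ATCC 33820	4	1
Atopobium vaginae BAA-55	2	1
Gardnerella vaginalis ATCC 14018	2	1
Propionibacterium acnes ATCC 6919	3	1
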