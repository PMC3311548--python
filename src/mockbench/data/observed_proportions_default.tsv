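taxon	method	mean_pct	sd_pct
Escherichia coli ATCC 47076	1	9.3	2.3
Escherichia coli ATCC 47076	2	8.6	2.0
Escherichia coli ATCC 47076	3	9.5	1.4
Escherichia coli ATCC 47076	4	6.2	1.6
Escherichia coli ATCC 47076	5	3.7	0.9
Escherichia coli ATCC 47076	6	5.8	1.9
Staphylococcus aureus ATCC 12600	1	7.5	1.0
Staphylococcus aureus ATCC 12600	2	11.4	1.2
Staphylococcus aureus ATCC 12600	3	5.0	1.1
Staphylococcus aureus ATCC 12600	4	11.4	2.6
Staphylococcus aureus ATCC 12600	5	3.4	0.9
Staphylococcus aureus ATCC 12600	6	4.6	1.2
Pseudomonas aeruginosa ATCC 10145	1	2.3	0.9
Pseudomonas aeruginosa ATCC 10145	2	2.7	0.9
Pseudomonas aeruginosa ATCC 10145	3	2.9	1.0
Pseudomonas aeruginosa ATCC 10145	4	1.2	0.7
Pseudomonas aeruginosa ATCC 10145	5	0.9	0.2
Pseudomonas aeruginosa ATCC 10145	6	2.4	0.9
Streptococcus agalactiae ATCC 12403	1	15.7	3.1
Streptococcus agalactiae ATCC 12403	2	14.8	1.4
Streptococcus agalactiae ATCC 12403	3	1.6	1.2
Streptococcus agalactiae ATCC 12403	4	19.4	2.8
Streptococcus agalactiae ATCC 12403	5	7.1	4.0
Streptococcus agalactiae ATCC 12403	6	15.7	3.3
Corynebacterium tuberculostearicum ATCC 35692	1	9.4	1.6
Corynebacterium tuberculostearicum ATCC 35692	2	9.6	2.2
Corynebacterium tuberculostearicum ATCC 35692	3	5.3	1.2
Corynebacterium tuberculostearicum ATCC 35692	4	13.8	1.8
Corynebacterium tuberculostearicum ATCC 35692	5	9.6	2.0
Corynebacterium tuberculostearicum ATCC 35692	6	15.3	2.5
Enterococcus faecalis ATCC 19433	1	6.1	1.5
Enterococcus faecalis ATCC 19433	2	5.9	1.6
Enterococcus faecalis ATCC 19433	3	10.4	3.2
Enterococcus faecalis ATCC 19433	4	7.6	2.5
Enterococcus faecalis ATCC 19433	5	6.3	1.5
Enterococcus faecalis ATCC 19433	6	10.2	2.1
Lactobacillus iners DSMZ 13335	1	21.5	4.1
Lactobacillus iners DSMZ 13335	2	18.9	3.7
Lactobacillus iners DSMZ 13335	3	45.8	2.3
Lactobacillus iners DSMZ 13335	4	27.6	6.4
Lactobacillus iners DSMZ 13335	5	48.0	9.2
Lactobacillus iners DSMZ 13335	6	37.7	6.3
Lactobacillus crispatus ATCC 33820	1	5.2	2.3
Lactobacillus crispatus ATCC 33820	2	7.0	2.6
Lactobacillus crispatus ATCC 33820	3	2.5	0.9
Lactobacillus crispatus ATCC 33820	4	4.0	1.3
Lactobacillus crispatus ATCC 33820	5	9.0	3.8
Lactobacillus crispatus ATCC 33820	6	3.6	1.5
Atopobium vaginae BAA-55	1	10.8	2.5
Atopobium vaginae BAA-55	2	8.3	1.7
Atopobium vaginae BAA-55	3	14.6	2.0
Atopobium vaginae BAA-55	4	2.7	1.0
Atopobium vaginae BAA-55	5	5.1	1.1
Atopobium vaginae BAA-55	6	1.9	1.2
Gardnerella vaginalis ATCC 14018	1	11.9	1.6
Gardnerella vaginalis ATCC 14018	2	11.6	0.9
Gardnerella vaginalis ATCC 14018	3	1.8	0.7
Gardnerella vaginalis ATCC 14018	4	3.4	1.4
Gardnerella vaginalis ATCC 14018	5	5.6	1.6
Gardnerella vaginalis ATCC 14018	6	0.5	0.3
Propionibacterium acnes ATCC 6919	1	0.3	0.3
Propionibacterium acnes ATCC 6919	2	1.2	0.8
Propionibacterium acnes ATCC 6919	3	0.7	0.3
Propionibacterium acnes ATCC 6919	4	2.7	0.8
Propionibacterium acnes ATCC 6919	5	1.2	0.5
Propionibacterium acnes ATCC 6919	6	2.3	1.6
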