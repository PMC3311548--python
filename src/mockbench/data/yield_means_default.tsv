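sample	method	mean_concentration
Escherichia coli ATCC 47076	1	2.96
Escherichia coli ATCC 47076	2	0.81
Escherichia coli ATCC 47076	3	0.88
Escherichia coli ATCC 47076	4	4.26
Escherichia coli ATCC 47076	5	3.47
Escherichia coli ATCC 47076	6	1.46
Staphylococcus aureus ATCC 12600	1	0.85
Staphylococcus aureus ATCC 12600	2	0.84
Staphylococcus aureus ATCC 12600	3	0.19
Staphylococcus aureus ATCC 12600	4	4.81
Staphylococcus aureus ATCC 12600	5	0.4
Staphylococcus aureus ATCC 12600	6	0.29
Pseudomonas aeruginosa ATCC 10145	1	2.38
Pseudomonas aeruginosa ATCC 10145	2	0.71
Pseudomonas aeruginosa ATCC 10145	3	0.86
Pseudomonas aeruginosa ATCC 10145	4	5.39
Pseudomonas aeruginosa ATCC 10145	5	2.07
Pseudomonas aeruginosa ATCC 10145	6	1.24
Streptococcus agalactiae ATCC 12403	1	2.5
Streptococcus agalactiae ATCC 12403	2	0.75
Streptococcus agalactiae ATCC 12403	3	0.05
Streptococcus agalactiae ATCC 12403	4	5.91
Streptococcus agalactiae ATCC 12403	5	0.46
Streptococcus agalactiae ATCC 12403	6	0.34
Corynebacterium tuberculostearicum ATCC 35692	1	1.38
Corynebacterium tuberculostearicum ATCC 35692	2	0.77
Corynebacterium tuberculostearicum ATCC 35692	3	0.19
Corynebacterium tuberculostearicum ATCC 35692	4	4.54
Corynebacterium tuberculostearicum ATCC 35692	5	0.79
Corynebacterium tuberculostearicum ATCC 35692	6	0.69
Enterococcus faecalis ATCC 19433	1	3.12
Enterococcus faecalis ATCC 19433	2	1.71
Enterococcus faecalis ATCC 19433	3	0.97
Enterococcus faecalis ATCC 19433	4	8.33
Enterococcus faecalis ATCC 19433	5	1.97
Enterococcus faecalis ATCC 19433	6	1.09
Lactobacillus iners DSMZ 13335	1	3.32
Lactobacillus iners DSMZ 13335	2	1.28
Lactobacillus iners DSMZ 13335	3	1.23
Lactobacillus iners DSMZ 13335	4	6.45
Lactobacillus iners DSMZ 13335	5	3.65
Lactobacillus iners DSMZ 13335	6	1.11
Lactobacillus crispatus ATCC 33820	1	2.22
Lactobacillus crispatus ATCC 33820	2	1.24
Lactobacillus crispatus ATCC 33820	3	0.27
Lactobacillus crispatus ATCC 33820	4	3.65
Lactobacillus crispatus ATCC 33820	5	1.16
Lactobacillus crispatus ATCC 33820	6	0.23
Atopobium vaginae BAA-55	1	1.66
Atopobium vaginae BAA-55	2	0.38
Atopobium vaginae BAA-55	3	0.51
Atopobium vaginae BAA-55	4	1.01
Atopobium vaginae BAA-55	5	0.73
Atopobium vaginae BAA-55	6	0.18
Gardnerella vaginalis ATCC 14018	1	1.65
Gardnerella vaginalis ATCC 14018	2	0.58
Gardnerella vaginalis ATCC 14018	3	0.09
Gardnerella vaginalis ATCC 14018	4	1.7
Gardnerella vaginalis ATCC 14018	5	0.62
Gardnerella vaginalis ATCC 14018	6	0.1
Propionibacterium acnes ATCC 6919	1	0.35
Propionibacterium acnes ATCC 6919	2	0.36
Propionibacterium acnes ATCC 6919	3	0.14
Propionibacterium acnes ATCC 6919	4	2.2
Propionibacterium acnes ATCC 6919	5	0.41
Propionibacterium acnes ATCC 6919	6	0.21
Mock community	1	1.52
Mock community	2	0.6
Mock community	3	0.37
Mock community	4	2.77
Mock community	5	1.04
Mock community	6	0.38
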