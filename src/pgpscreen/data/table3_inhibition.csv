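isolate_id,P. hypobrunnea,F. solani,R. solani,F. oxysporum,C. capsici,P. lamaensis,P. theae,C. eragrostidis,N. sphaerica,G. cingulata
DNRA1,-,-,-,-,-,-,-,-,-,-
DNRA2,-,-,-,-,-,-,-,-,-,-
DNRA3,-,-,58.4 ± 0.4,-,-,-,-,-,46.7 ± 0.6,-
DNRA4,49.2 ± 0.9,46.6 ± 0.4,-,59.5 ± 0.1,41.2 ± 0.2,62.7 ± 0.6,-,-,-,-
DNRA5,54.3 ± 1.3,-,-,62.5 ± 0.8,46.5 ± 0.1,-,42.1 ± 0.4,-,45.2 ± 0.4,-
DNLA1,-,61.2 ± 0.6,-,49.6 ± 0.1,-,-,56.3 ± 1.1,-,-,-
DNLA2,-,-,-,-,-,-,-,-,-,-
DNLA13,82.4 ± 0.8,80 ± 1.2,58.4 ± 0.6,64.5 ± 0.3,55.7 ± 0.4,58.9 ± 0.6,48.7 ± 0.6,61.3 ± 0.8,84.5 ± 0.2,71.2 ± 0.8
DCRA1,67.5 ± 0.6,-,31.6 ± 0.4,53.4 ± 0.4,49.3 ± 0.2,65.9 ± 1.3,43.1 ± 0.4,-,-,58.7 ± 0.1
DCRA2,52.3 ± 0.4,-,49.5 ± 0.2,58.2 ± 0.3,27.2 ± 0.4,-,-,-,-,-
DCRA3,-,-,-,-,-,-,-,-,-,-
DCLA1,51.5 ± 0.3,58.5 ± 0.4,-,43.6 ± 0.9,-,-,40.2 ± 0.6,-,-,-
DCLA2,-,-,-,-,-,-,-,-,-,-
DCLA5,-,46.2 ± 0.9,58.6 ± 0.8,43.4 ± 0.2,-,48.5 ± 0.2,-,-,-,-
DMRA1,-,-,-,-,-,-,-,-,-,-
DMRA2,-,-,-,-,-,-,-,-,-,-
DMRA3,-,-,-,-,-,-,-,-,-,-
DMLA1,-,-,53.2 ± 0.2,-,57.4 ± 0.4,-,59.2 ± 0.7,-,-,-
DMLA8,-,-,-,-,-,-,-,-,-,-
DDRA1,-,-,-,-,-,-,-,-,-,-
DDRA2,43.3 ± 0.7,-,48.5 ± 0.6,57.3 ± 0.4,43.2 ± 0.2,-,55.3 ± 0.1,-,-,-
DDRA3,-,-,-,-,-,-,-,-,-,-
DDRA4,-,59.3 ± 0.3,42.1 ± 1.1,46.2 ± 0.4,-,-,-,-,38.6 ± 0.4,-
DDLA1,-,-,-,-,-,-,-,-,-,-
DDLA2,-,-,-,-,-,-,-,-,-,-
DFRA1,-,-,-,-,-,-,-,-,-,-
DFRA2,-,-,-,-,-,-,-,-,-,-
DFRA3,46.6 ± 0.8,-,-,-,-,-,-,-,64.3 ± 0.4,55 ± 0.9
DFLA1,-,61.3 ± 0.4,41.9 ± 0.9,43.2 ± 0.9,51.2 ± 0.1,40 ± 0.2,51.1 ± 0.3,-,-,-
DFLA4,-,65.71 ± 1.1,28.2 ± 0.6,46.7 ± 0.3,-,38.8 ± 0.3,-,-,-,45.6 ± 0.4
CARA1,-,-,-,-,-,-,-,-,-,-
CARA2,-,-,52.1 ± 0.3,-,-,-,41.2 ± 0.4,-,-,-
CARA3,-,-,-,-,-,-,-,-,-,-
CALA1,-,-,-,-,-,-,-,-,-,-
RRRA1,-,-,-,-,-,-,-,-,-,-
RRR46,53.2 ± 0.3,-,-,62 ± 0.6,64.4 ± 0.4,60 ± 0.8,-,-,51.1 ± 0.4,41.8 ± 0.2
RRLA1,-,44.4 ± 0.2,-,-,58.6 ± 0.2,-,-,44.2 ± 0.4,-,-
RVRA1,41.9 ± 1.1,39.6 ± 0.8,47.7 ± 0.4,26.1 ± 0.9,-,-,-,-,51.3 ± 0.8,50 ± 0.4
RVRA2,-,-,-,-,61.1 ± 0.4,31.5 ± 0.2,-,-,-,56.6 ± 0.6
RVRA3,-,-,-,43.2 ± 0.8,51.3 ± 0.3,58.1 ± 0.6,-,45 ± 0.4,-,-
RVRA4,-,-,-,57 ± 0.4,48.5 ± 0.5,43.1 ± 0.1,41.2 ± 0.4,31.2 ± 0.4,-,-
RVRA6,-,-,-,-,-,-,-,-,-,35.4 ± 0.3
RVRA7,42.1 ± 1.0,51.1 ± 1.5,68.3 ± 0.5,72.3 ± 1.3,77.2 ± 0.6,62.4 ± 1.1,56.5 ± 1.2,74.4 ± 0.4,-,-
RVRA8,-,58.8 ± 0.4,-,-,53.3 ± 1.4,-,67.6 ± 0.4,-,-,58.4 ± 0.4
RVLA1,-,-,-,-,-,-,-,-,-,-
MORA11,-,-,-,-,-,-,-,-,-,-
MOLA1,-,-,-,-,-,-,51.2 ± 0.4,-,-,-
VCLA1,-,-,-,-,-,-,-,-,-,-
VCLA3,90.2 ± 0.7,61.1 ± 0.6,71.1 ± 1.2,45.5 ± 1.4,88.8 ± 1.3,91.1 ± 1.7,65.51 ± 1.2,83.2 ± 0.8,-,-
VCRA1,-,-,-,-,-,-,-,-,-,-
VCRA2,83.3 ± 1.2,92.2 ± 1.2,80 ± 0.8,62.6 ± 1.1,81.1 ± 1.3,52.1 ± 0.5,78.3 ± 0.4,55.5 ± 0.9,85.1 ± 0.4,89.2 ± 0.2
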