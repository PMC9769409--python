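isolate_id,iaa,p_solub,ammonia,n2_fixation,siderophore,acc_deaminase,chitinase,protease,cellulase,pectinase
DNRA1,20.7 ± 0.4,289.7 ± 11.1,2.1 ± 0.1,-,ND,+,-,+,-,-
DNRA2,ND,ND,3.4 ± 0.1,-,ND,+,-,-,-,+
DNRA3,13.6 ± 0.2,134.3 ± 5.2,3.3 ± 0.2,+,21.3 ± 0.2,+,-,+,-,-
DNRA4,ND,80.5 ± 6.0,3.1 ± 0.5,-,ND,+,+,+,+,-
DNRA5,32.2 ± 0.5,112.4 ± 10,ND,-,ND,+,+,-,-,+
DNLA1,14.6 ± 0.08,ND,3.6 ± 0.1,+,ND,+,+,+,+,+
DNLA2,ND,169.6 ± 6.2,2.3 ± 0.1,-,ND,-,-,-,-,-
DNLA13,5.8 ± 0.08,123.5 ± 2.8,ND,+,ND,-,+,-,-,-
DCRA1,ND,61.1 ± 4.4,ND,-,ND,-,-,+,-,+
DCRA2,24.3 ± 0.1,89.8 ± 3.0,4.5 ± 0.2,+,ND,-,+,+,+,-
DCRA3,ND,193.1 ± 9.2,3.7 ± 0.3,+,ND,+,-,+,-,-
DCLA1,12.8 ± 0.2,ND,ND,-,40.5 ± 0.6,-,+,-,-,-
DCLA2,ND,ND,3.1 ± 0.2,-,ND,-,-,-,+,-
DCLA5,14.4 ± 0.06,ND,5.9 ± 0.2,-,32.1 ± 0.3,-,-,+,-,-
DMRA1,10 ± 0.05,76.3 ± 4.2,ND,-,53.2 ± 0.5,+,-,-,-,-
DMRA2,ND,181.2 ± 2.3,3.9 ± 0.3,-,ND,-,-,+,-,+
DMRA3,18.5 ± 0.2,ND,3.4 ± 0.6,-,ND,-,-,-,-,-
DMLA1,29.1 ± 0.03,ND,2.7 ± 0.2,+,ND,-,-,-,-,-
DMLA8,7.5 ± 0.1,ND,0.9 ± 0.1,-,ND,-,-,+,+,-
DDRA1,22.7 ± 0.1,124.9 ± 0.8,ND,-,ND,-,-,-,-,-
DDRA2,10.3 ± 0.2,ND,1.5 ± 0.1,-,26.1 ± 0.8,-,+,-,-,-
DDRA3,ND,180.2 ± 1.5,ND,-,ND,-,-,+,+,+
DDRA4,ND,ND,3.1 ± 0.1,-,ND,-,+,-,-,-
DDLA1,ND,ND,1.3 ± 0.2,-,ND,-,-,-,+,-
DDLA2,ND,ND,2.2 ± 0.2,-,39.2 ± 0.3,+,-,+,-,-
DFRA1,ND,ND,ND,-,ND,-,-,-,-,-
DFRA2,ND,ND,2.5 ± 0.3,+,ND,-,-,-,+,-
DFRA3,18.6 ± 0.08,85.8 ± 3.2,3.2 ± 1.1,+,59.4 ± 0.4,+,-,-,-,-
DFLA1,9.4 ± 0.2,93.2 ± 2.3,1.9 ± 0.2,-,ND,+,+,+,-,-
DFLA4,ND,ND,ND,+,ND,-,+,-,-,-
CARA1,23.3 ± 0.1,132.5 ± 2.3,3.9 ± 0.4,-,ND,-,-,-,-,-
CARA2,ND,ND,ND,+,ND,-,-,-,-,-
CARA3,ND,ND,ND,-,ND,-,-,+,-,-
CALA1,ND,ND,2.5 ± 0.4,-,ND,-,-,-,-,-
RRRA1,ND,96.3 ± 2.0,2.6 ± 0.1,-,25.7 ± 0.6,-,-,-,-,-
RRR46,8.4 ± 0.2,213.2 ± 0.3,2.3 ± 0.1,-,61.2 ± 0.2,-,+,+,+,-
RRLA1,ND,ND,4.8 ± 0.2,-,ND,-,-,+,-,+
RVRA1,4 ± 0.08,ND,2.9 ± 0.1,+,ND,-,+,-,-,-
RVRA2,33.9 ± 0.4,ND,1.3 ± 0.1,+,ND,+,+,+,-,+
RVRA3,27.1 ± 0.1,148.3 ± 1.2,2.6 ± 0.1,-,ND,-,+,+,+,-
RVRA4,11.3 ± 0.2,103.6 ± 0.4,3.1 ± 0.2,+,38.3 ± 0.5,-,+,-,-,-
RVRA6,ND,ND,ND,+,ND,-,-,+,-,-
RVRA7,38.2 ± 0.2,239.1 ± 0.8,4.9 ± 0.2,+,39.7 ± 0.2,+,+,-,-,-
RVRA8,ND,81.2 ± 0.2,ND,-,ND,-,+,-,-,+
RVLA1,19.1 ± 0.8,ND,1.5 ± 0.1,-,ND,-,-,-,-,-
MORA11,12.4 ± 0.1,90.3 ± 1.2,2.6 ± 0.1,-,ND,-,-,+,-,-
MOLA1,8.4 ± 0.1,ND,ND,-,21.3 ± 0.4,-,-,-,-,-
VCLA1,ND,ND,ND,+,ND,-,-,-,+,+
VCLA3,43.8 ± 0.2,258.2 ± 6.7,4.1 ± 0.4,+,31.3 ± 0.2,+,+,+,+,-
VCRA1,ND,ND,4.1 ± 0.4,-,ND,-,-,-,-,+
VCRA2,ND,115.6 ± 1.1,ND,-,ND,-,+,+,-,-
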