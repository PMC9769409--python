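isolate_id,iaa,p_solub,ammonia,n2_fixation,acc_deaminase,siderophore,chitinase,P. hypobrunnea,F. solani,R. solani,F. oxysporum,C. capsici,P. lamaensis,P. theae,C. eragrostidis,N. sphaerica,G. cingulata,total,rank
VCLA3,3,3,1,1,1,1,1,3,3,3,2,3,3,3,3,0,0,34,1
RVRA7,3,3,1,1,1,1,1,2,2,3,3,3,3,2,3,0,0,32,2
VCRA2,0,1,0,0,0,0,1,3,3,2,3,2,2,2,3,3,3,30,3
DNLA13,1,2,0,1,0,0,1,1,3,2,3,3,2,2,3,3,3,30,3
RRR46,1,3,1,0,0,1,1,2,0,0,3,3,2,0,0,2,2,21,4
DNRA5,3,2,0,0,1,0,1,2,0,0,3,2,0,2,0,2,0,18,5
DFLA1,1,1,1,0,1,0,1,0,3,2,2,2,2,2,0,0,0,18,5
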