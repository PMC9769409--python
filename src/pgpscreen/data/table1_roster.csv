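isolate_id,colony_morphology,aerial_mycelia_color,substrate_mycelia_color,diffusible_pigment,color_series,texture,tissue
DNRA1,"Irregular, umbonate",Gray,Gray,NP,Gray,Dry,root
DNRA2,"Irregular, raised",White,White,NP,White,Rough,root
DNRA3,Irregular flat,White,Brown,NP,White,Smooth,root
DNRA4,Irregular umbonate,Off white,Off white,NP,White,Dry,root
DNRA5,"Irregular, raised",White,Brown,NP,White,Rough. Spongy,root
DNLA1,"Irregular, umbonate",White,White,NP,White,Dry,leaf
DNLA2,Irregular raised,Gray,Gray,NP,Gray,"Dry, Sticky",leaf
DNLA13,Irregular raised,Blackish gray,Dark brown,NP,Gray,Dry,leaf
DCRA1,Circular umbonate,White,Light brown,NP,White,Dry,root
DCRA2,Circular raised,Off white,Gray,NP,White,Dry,root
DCRA3,"Undulate, flat",White,Brown,NP,White,"Rough, dry",root
DCLA1,Irregular raised,Off white,Light brown,NP,White,Dry,leaf
DCLA2,Irregular undulate,Black,Black,NP,Gray,Rough dry,leaf
DCLA5,"Curled, umbonate",Brown,Brown,NP,Brown,"Rough, dry",leaf
DMRA1,Irregular raised,Off white,Light cream,NP,White,Dry,root
DMRA2,Circular umbonate,Gray,Blackish gray,NP,Gray,Dry,root
DMRA3,Irregular raised,Gray,Gray,NP,Gray,Dry,root
DMLA8,Irregular umbonate,Off white,Off white,NP,White,Rough dry,leaf
DDRA1,Irregular umbonate,Cream white,Brown,NP,White,Dry,root
DDRA2,Circular umbonate,Brown,Brown,NP,Brown,Dry,root
DDRA3,Circular raised,Orange,Cream white,NP,Orange,Dry,root
DDRA4,"scalloped, raised",Orange,Orange,Yellow,Orange,Smooth,root
DDLA1,Circular pulvinate,Brownish-yellow,Light yellow,Light brown,Yellow,Dry,leaf
DDLA2,"Irregular, umbonate",Off white,Off white,NP,White,Dry,leaf
DFRA1,Irregular raised,Grey,Light brown,NP,Gray,Dry,root
DFRA2,Undulate raised,White,White,NP,White,Dry,root
DFRA3,Circular raised,Gray,Light brown,NP,Gray,Dry,root
DFLA1,"Circular, raised",White,Orange,yellow,White,Rough,leaf
DFLA4,"Curled, raised",Pink,Yellow,NP,Pink,"Rough, powdery",leaf
CARA1,Circular flat,Yellow,White,NP,Yellow,Dry,root
CARA2,"Circular, umbonate",Gray,Light brown,NP,Gray,Dry,root
CARA3,"Irregular, Pulvinate",White,Light brown,NP,White,Dry,root
CALA1,Undulate flat,Peach,Peach,NP,Orange,Dry,root
RRRA1,Irregular flat,Gray,Brown,NP,Gray,Dry/spongy,root
RRLA1,Circular umbonate,Orange,Light brown,Light brown,Orange,Dry,leaf
RRR46,Irregular umbonate,Off white,White,NP,White,Dry,root
RVRA1,Irregular convex,Red,Red,Light pink,Red,Dry,root
RVRA2,"Irregular, raised",Cream white,Light brown,NP,White,Dry,root
RVRA3,"Circular, umbonate",Yellow,Brown,NP,Yellow,Dry,root
RVRA4,"Circular, convex",Pink,Yellow,NP,Pink,Dry,root
RVRA6,Undulate raised,yellow,Light brown,NP,Yellow,Dry,root
RVRA7,"Circular, crateriform",White,white,NP,White,Rough dry,root
RVRA8,Irregular pulvinate,White,Light brown,Light brown,White,Rough dry,root
RVLA1,Circular convex,Dark gray,Dark brown,NP,Gray,Rough dry,leaf
MORA11,Irregular raised,Dark gray,Black,Black,Gray,Dry/powdery,root
MORA2,Circular crateriform,Light brown,Light brown,NP,Brown,Dry,root
MOLA1,"Irregular, pulvinate",Gray,Brown,Light brown,Gray,Dry,leaf
VCLA1,Circular raised,Off white,Light brown,NP,White,Dry,leaf
VCLA3,Undulate raised,Gray,Light brown,NP,Gray,Dry,leaf
VCRA1,Irregular umbonate,Cream white,Cream white,NP,White,Dry,root
VCRA2,Circular raised,White,Yellow,Yellow,White,Rough dry,root
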