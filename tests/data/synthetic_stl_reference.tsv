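seasonal	trend
-0.257780410828331	0.528829554963365
-0.427068338962913	0.526769545647746
-0.384115727544848	0.524709536332126
-0.976704524680897	0.522649527016506
0.383479332525632	0.520589517700886
-0.0397689413767216	0.518529508385266
-0.383109142996781	0.516469499069646
0.219388788157171	0.514409489754026
0.308469829619769	0.512349480438406
0.623211867409006	0.510343787692816
0.344331873712801	0.508338094947226
0.51064700799435	0.506332402201635
0.489100814317247	0.504326709456045
0.756941014783028	0.502321016710455
0.645241788636234	0.500315323964864
1.25906235854633	0.498309631219274
0.957617895687847	0.496303938473684
0.747690738812295	0.494251329540944
0.693086872045244	0.492198720608205
1.04840480564148	0.490146111675466
1.32204304874766	0.488093502742726
0.922513068844982	0.486040893809987
1.02392586755752	0.483988284877248
1.34064790101248	0.481935675944508
0.213885020318925	0.479883067011769
0.143336976259503	0.477720998174249
0.599159615296448	0.47555892933673
0.554133624633374	0.47339686049921
0.60462349025513	0.47123479166169
0.512499880915475	0.469072722824171
0.334612910900779	0.466910653986651
-0.360752119104246	0.464748585149131
0.0755458074253122	0.462586516311612
0.219716803418892	0.460701721689493
-0.191844759634755	0.458816927067374
-0.385860543979621	0.456932132445255
-0.612146935530328	0.455047337823137
-0.474992262013986	0.453162543201018
-0.450451661306798	0.451277748578899
-0.648267369160785	0.44939295395678
-0.909054208897949	0.447508159334661
-1.06334269127199	0.447229202075908
-0.75965535602124	0.446950244817154
-1.38295278687151	0.446671287558401
-0.935163584536616	0.446392330299647
-1.1212003325893	0.446113373040893
-1.03420523340911	0.44583441578214
-1.04638191422776	0.445555458523386
-1.06810109232656	0.445276501264632
-0.690251382661424	0.445328025860346
-0.80201879764717	0.445379550456061
-0.448128885869087	0.445431075051775
-0.257780410828331	0.445482599647489
-0.427068338962913	0.445534124243203
-0.384115727544848	0.445585648838917
-0.976704524680897	0.445637173434631
0.383479332525632	0.445688698030345
-0.0397689413767216	0.446149762525606
-0.383109142996781	0.446610827020868
0.219388788157171	0.447071891516129
0.308469829619769	0.44753295601139
0.623211867409006	0.447994020506651
0.344331873712801	0.448455085001913
0.51064700799435	0.448916149497174
0.489100814317247	0.449377213992435
0.756941014783028	0.450519866548919
0.645241788636234	0.451662519105403
1.25906235854633	0.452805171661887
0.957617895687847	0.453947824218371
0.747690738812295	0.455090476774855
0.693086872045244	0.456233129331339
1.04840480564148	0.457375781887824
1.32204304874766	0.458518434444308
0.922513068844982	0.459396192337359
1.02392586755752	0.46027395023041
1.34064790101248	0.461151708123462
0.213885020318925	0.462029466016513
0.143336976259503	0.462907223909565
0.599159615296448	0.463784981802616
0.554133624633374	0.464662739695667
0.60462349025513	0.465540497588719
0.512499880915475	0.466715445809323
0.334612910900779	0.467890394029926
-0.360752119104246	0.46906534225053
0.0755458074253122	0.470240290471134
0.219716803418892	0.471415238691738
-0.191844759634755	0.472590186912342
-0.385860543979621	0.473765135132945
-0.612146935530328	0.474940083353549
-0.474992262013986	0.475273132537918
-0.450451661306798	0.475606181722287
-0.648267369160785	0.475939230906655
-0.909054208897949	0.476272280091024
-1.06334269127199	0.476605329275393
-0.75965535602124	0.476938378459762
-1.38295278687151	0.47727142764413
-0.935163584536616	0.477604476828499
-1.1212003325893	0.476753231747104
-1.03420523340911	0.475901986665709
-1.04638191422776	0.475050741584314
-1.06810109232656	0.474199496502918
-0.690251382661424	0.473348251421523
-0.80201879764717	0.472497006340128
-0.448128885869087	0.471645761258733
-0.257780410828331	0.470794516177338
-0.427068338962913	0.469140604094324
-0.384115727544848	0.46748669201131
-0.976704524680897	0.465832779928296
0.383479332525632	0.464178867845282
-0.0397689413767216	0.462524955762268
-0.383109142996781	0.460871043679254
0.219388788157171	0.459217131596241
0.308469829619769	0.457563219513227
0.623211867409006	0.456296831277156
0.344331873712801	0.455030443041086
0.51064700799435	0.453764054805016
0.489100814317247	0.452497666568945
0.756941014783028	0.451231278332875
0.645241788636234	0.449964890096805
1.25906235854633	0.448698501860734
0.957617895687847	0.447432113624664
0.747690738812295	0.44652630163953
0.693086872045244	0.445620489654396
1.04840480564148	0.444714677669262
1.32204304874766	0.443808865684129
0.922513068844982	0.442903053698995
1.02392586755752	0.441997241713861
1.34064790101248	0.441091429728727
0.213885020318925	0.440185617743593
0.143336976259503	0.439206028157603
0.599159615296448	0.438226438571612
0.554133624633374	0.437246848985621
0.60462349025513	0.436267259399631
0.512499880915475	0.43528766981364
0.334612910900779	0.434308080227649
-0.360752119104246	0.433328490641658
0.0755458074253122	0.432348901055668
0.219716803418892	0.431293792679777
-0.191844759634755	0.430238684303886
-0.385860543979621	0.429183575927996
-0.612146935530328	0.428128467552105
-0.474992262013986	0.427073359176214
-0.450451661306798	0.426018250800324
-0.648267369160785	0.424963142424433
-0.909054208897949	0.423908034048542
-1.06334269127199	0.422940479929255
-0.75965535602124	0.421972925809969
-1.38295278687151	0.421005371690682
-0.935163584536616	0.420037817571396
-1.1212003325893	0.419070263452109
-1.03420523340911	0.418102709332822
-1.04638191422776	0.417135155213536
-1.06810109232656	0.416167601094249
-0.690251382661424	0.415276104324884
-0.80201879764717	0.414384607555519
-0.448128885869087	0.413493110786154
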