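&FCI NORB=8,NELEC=10,MS2=0,
  ORBSYM=1,1,1,1,1,1,1,1,
  ISYM=1,
&END
 8.1938430597714651e-01   1   1   1   1
 5.3785070232573860e-02   2   1   2   1
 5.1835325004784005e-01   2   2   1   1
 5.3397069696160560e-01   2   2   2   2
 1.4394453948219701e-01   3   1   1   1
 6.0471223092911502e-03   3   1   2   2
 6.6553405140271291e-02   3   1   3   1
-9.0624855317644817e-02   3   2   2   1
 2.0735732746884078e-01   3   2   3   2
 5.6432841402312239e-01   3   3   1   1
 5.3885803814010402e-01   3   3   2   2
 3.2330613550620682e-02   3   3   3   1
 5.6121574592115986e-01   3   3   3   3
 1.0194766985001759e-01   4   1   4   1
 4.3313493594503559e-02   4   2   4   2
-1.2086140347847068e-02   4   3   4   1
 2.4411361142951858e-02   4   3   4   3
 6.3658653420550548e-01   4   4   1   1
 4.9569940736275347e-01   4   4   2   2
 6.2753364014364613e-02   4   4   3   1
 5.0656809077073583e-01   4   4   3   3
 5.8168334060287274e-01   4   4   4   4
 1.0194766985001741e-01   5   1   5   1
 4.3313493594503462e-02   5   2   5   2
-1.2086140347847064e-02   5   3   5   1
 2.4411361142951858e-02   5   3   5   3
 2.3302249172467725e-02   5   4   5   4
 6.3658653420550482e-01   5   5   1   1
 4.9569940736275298e-01   5   5   2   2
 6.2753364014364529e-02   5   5   3   1
 5.0656809077073517e-01   5   5   3   3
 5.3507884225793667e-01   5   5   4   4
 5.8168334060287130e-01   5   5   5   5
-3.9834666087025884e-02   6   1   4   2
-6.5990989243695816e-06   6   1   5   2
 4.6277434507935339e-02   6   1   6   1
-6.9319597898083535e-02   6   2   4   1
 3.3933659549500131e-02   6   2   4   3
-1.1483637968192820e-05   6   2   5   1
 5.6215251244175910e-06   6   2   5   3
 7.8384557662853488e-02   6   2   6   2
 3.4269426552777031e-02   6   3   4   2
 5.6771490291317341e-06   6   3   5   2
-2.2820457039721222e-02   6   3   6   1
 3.5823486474694764e-02   6   3   6   3
-9.2654999020279474e-02   6   4   2   1
 1.4752998853308391e-01   6   4   3   2
 1.8354375376617435e-01   6   4   6   4
-1.5349432151242158e-05   6   5   2   1
 2.4440144333331484e-05   6   5   3   2
 2.7470850436913982e-05   6   5   6   4
 1.7719277304195941e-02   6   5   6   5
 6.4372889215392648e-01   6   6   1   1
 5.4700824937781467e-01   6   6   2   2
 4.8847316204262033e-02   6   6   3   1
 5.5442869895856151e-01   6   6   3   3
 6.0113794326863013e-01   6   6   4   4
 7.2579306415112870e-06   6   6   5   4
 5.5732632005081728e-01   6   6   5   5
 6.5671126278562175e-01   6   6   6   6
-6.5990989242856559e-06   7   1   4   2
 3.9834666087025801e-02   7   1   5   2
 4.6277434507935304e-02   7   1   7   1
-1.1483637968038208e-05   7   2   4   1
 5.6215251244471948e-06   7   2   4   3
 6.9319597898083340e-02   7   2   5   1
-3.3933659549500055e-02   7   2   5   3
 7.8384557662853099e-02   7   2   7   2
 5.6771490291231951e-06   7   3   4   2
-3.4269426552776920e-02   7   3   5   2
-2.2820457039721135e-02   7   3   7   1
 3.5823486474694619e-02   7   3   7   3
-1.5349432151138013e-05   7   4   2   1
 2.4440144333204957e-05   7   4   3   2
 2.7470850436765951e-05   7   4   6   4
-1.7719268202432203e-02   7   4   6   5
 1.7719277304195917e-02   7   4   7   4
 9.2654999020279419e-02   7   5   2   1
-1.4752998853308372e-01   7   5   3   2
-1.4810520825954607e-01   7   5   6   4
-2.7470850436960111e-05   7   5   6   5
-2.7470850436763732e-05   7   5   7   4
 1.8354375376617404e-01   7   5   7   5
 7.2579306408604353e-06   7   6   4   4
-2.1905811608906030e-02   7   6   5   4
-7.2579306419906610e-06   7   6   5   5
 2.6341393614194887e-02   7   6   7   6
 6.4372889215392504e-01   7   7   1   1
 5.4700824937781345e-01   7   7   2   2
 4.8847316204262123e-02   7   7   3   1
 5.5442869895856040e-01   7   7   3   3
 5.5732632005081673e-01   7   7   4   4
-7.2579306413956111e-06   7   7   5   4
 6.0113794326862813e-01   7   7   5   5
 6.0402847555723060e-01   7   7   6   6
 6.5671126278561898e-01   7   7   7   7
 5.9956116655628548e-02   8   1   2   1
-5.9710890954427456e-02   8   1   3   2
-1.1368882273479694e-01   8   1   6   4
-1.8833941928296283e-05   8   1   6   5
-1.8833941928332621e-05   8   1   7   4
 1.1368882273479694e-01   8   1   7   5
 1.3318501264610128e-01   8   1   8   1
 6.4055362788354442e-02   8   2   1   1
-2.1328433608267614e-02   8   2   2   2
 2.8357014309077444e-02   8   2   3   1
-2.3344856403527375e-02   8   2   3   3
 3.6409736806066344e-02   8   2   4   4
 3.6409736806066198e-02   8   2   5   5
 2.3341538999235082e-02   8   2   6   6
 2.3341538999235040e-02   8   2   7   7
 3.9219244683936658e-02   8   2   8   2
 5.4592598740384676e-02   8   3   2   1
-1.1301960956944368e-01   8   3   3   2
-9.4510020794514663e-02   8   3   6   4
-1.5656739162934098e-05   8   3   6   5
-1.5656739162705731e-05   8   3   7   4
 9.4510020794514524e-02   8   3   7   5
 7.6800036761828477e-02   8   3   8   1
 9.3898325353321613e-02   8   3   8   3
 2.2882131629444569e-02   8   4   4   2
-3.5698749378745454e-02   8   4   6   1
 4.0452452218954060e-03   8   4   6   3
-5.9139338111580599e-06   8   4   7   1
 6.7014427428000287e-07   8   4   7   3
 3.5211063855502739e-02   8   4   8   4
 2.2882131629444465e-02   8   5   5   2
-5.9139338109979063e-06   8   5   6   1
 6.7014427410035015e-07   8   5   6   3
 3.5698749378745384e-02   8   5   7   1
-4.0452452218953444e-03   8   5   7   3
 3.5211063855502642e-02   8   5   8   5
-6.2288974081349299e-02   8   6   4   1
-3.8673992519101341e-04   8   6   4   3
-1.0318929270139113e-05   8   6   5   1
-6.4068191829760774e-08   8   6   5   3
 3.5545510681081742e-02   8   6   6   2
 5.0291078922924962e-02   8   6   8   6
-1.0318929270448990e-05   8   7   4   1
-6.4068191614909292e-08   8   7   4   3
 6.2288974081349167e-02   8   7   5   1
 3.8673992519104458e-04   8   7   5   3
 3.5545510681081624e-02   8   7   7   2
 5.0291078922924858e-02   8   7   8   7
 7.9877134870438371e-01   8   8   1   1
 5.6524765204107263e-01   8   8   2   2
 1.2356815004921815e-01   8   8   3   1
 6.1087522083308432e-01   8   8   3   3
 6.4029357136531229e-01   8   8   4   4
 6.4029357136531162e-01   8   8   5   5
 6.8111453466232807e-01   8   8   6   6
 6.8111453466232652e-01   8   8   7   7
 3.8882423531811157e-02   8   8   8   2
 8.4718921421650906e-01   8   8   8   8
-6.6786502727461103e+00   1   1   0   0
 1.2582368354640713e-12   2   1   0   0
-5.0563113934485999e+00   2   2   0   0
-5.3539407542191875e-01   3   1   0   0
-5.1071556065051240e+00   3   3   0   0
-5.3372662717860697e+00   4   4   0   0
-5.3372662717860608e+00   5   5   0   0
-1.1036348603372260e-12   6   1   0   0
-5.1426157740894984e+00   6   6   0   0
-5.1426157740894869e+00   7   7   0   0
-2.0784750064861274e-01   8   2   0   0
-4.9534089012755569e+00   8   8   0   0
-7.7353494809510167e+01   0   0   0   0
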