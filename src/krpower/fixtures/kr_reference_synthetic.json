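[{"seed":101,"n_complete":[6,6],"n_incomplete":[0,0],"p":4,"p_inc":0,"y":{"1":[1.226425364903753,-0.0009803344712160378,0.8883229685280398,0.9847327267982167],"2":[2.792756143188667,2.061231972808485,3.090994577075411,1.950706922935436],"3":[0.7316036634585872,2.954203643556679,0.05962840471017739,1.289764720270747],"4":[-0.04309270533136189,0.8651275328520013,-0.01100832087345849,-1.243645780637132],"5":[1.544766438214954,0.5682637878769599,-0.6276774258124417,1.580680156933895],"6":[0.05667742501004897,-0.5297102886994425,0.05684878076031724,0.08774538343071664],"7":[1.174089196954139,1.902802950854632,-1.178169290033392,2.084790584323244],"8":[-0.5563904460210956,0.1959609402108701,-2.395979030392893,-0.275905148755668],"9":[1.240672592257769,-1.83686855910872,0.02295402966261462,-0.622924857120505],"10":[0.9718631912503443,-0.3031550090233169,0.1128376475907298,-1.080949798199261],"11":[-1.42472644307783,-0.5723542784001954,-2.547157927838394,-0.4011975650965871],"12":[-0.8858058262972488,0.07862242357226945,0.1225357673127632,-1.479049928773376]},"kr_ddf":9.999999999999993,"kr_F":5.457017503746918,"kr_p":0.04162055949027736,"kr_scaling":1,"reml_vb":0.5070868956447793,"reml_ve":0.962147747965428},{"seed":202,"n_complete":[5,5],"n_incomplete":[3,3],"p":4,"p_inc":2,"y":{"1":[-1.338169907300793,-1.234076552213123,-1.744725439581574,-1.04370383604695],"2":[-2.122424515152417,-3.279136603225331,-1.032778041809509,-0.8771718959466003],"3":[1.772222361216079,-0.1835430787397773,0.4853340948089313,2.262010368534246],"4":[2.387188623175155,-0.1486354170140729,1.370032851341878,1.857751706671736],"5":[2.190122572320178,2.212707833445098,2.059098419329532,1.66821338009863],"6":[0.9560888792241176,0.797192648573344,-0.2822324151292241,3.125075706427956],"7":[3.595248702382429,1.865785822762536,1.240265797548475,2.292613921629089],"8":[-0.1148445612783763,1.256318096465962,-1.005887320982882,0.004309537404591612],"9":[3.350915320238185,2.645155386766994,3.270695960355258,3.840537756159486],"10":[2.350435692676098,-0.6233473512061338,0.7491998364401061,-0.1649481401380374],"11":[0.6667083870287589,-0.5255191131298566],"12":[4.653818642800392,4.854115504976047],"13":[1.07334398181169,1.400350292096113],"14":[0.8594987971548644,0.7579240125007684],"15":[-1.691771325218852,0.2009055349122535],"16":[-0.1137101703500732,-1.319532868007919]},"kr_ddf":13.97541806270752,"kr_F":0.001551409319870805,"kr_p":0.9691382437622381,"kr_scaling":1,"reml_vb":2.745954764486064,"reml_ve":0.9042254238349133},{"seed":303,"n_complete":[8,8],"n_incomplete":[0,0],"p":3,"p_inc":0,"y":{"1":[0.4370547134502878,0.5638101339240997,0.1847473722357679],"2":[1.614103801899533,-1.475513983005609,-0.834800156052252],"3":[1.044520110536725,1.540882704768987,1.447397786030895],"4":[2.275032083627375,0.3828199059605361,0.07491039501746322],"5":[0.5265738133853646,0.577187357555343,1.786116692909359],"6":[1.380714763999647,-0.2299989616610025,0.1372769776124035],"7":[1.300514678601449,0.8802642905052248,-0.2095114355952068],"8":[3.151948684704219,1.593796891693973,1.303232778341844],"9":[0.843520898386741,-0.276633746907966,-1.497981848516767],"10":[1.446542271252662,-0.3944741450420275,0.6855997171365331],"11":[1.957759717800671,2.205311476925714,0.9689791025783774],"12":[-1.796666608965108,0.6286567910616514,-2.242861586854812],"13":[-0.54845629426863,0.6523402225356258,1.611949181737321],"14":[-2.290367868303701,-3.124335841232747,-4.290028878661381],"15":[-1.53576576174771,1.320462916668755,1.072577351609124],"16":[-2.245982385040204,-0.3649392271538847,0.3346551613630924]},"kr_ddf":14.00000000000004,"kr_F":3.616200469757592,"kr_p":0.07799980037006195,"kr_scaling":1,"reml_vb":0.9460258985035673,"reml_ve":1.15689876909755},{"seed":404,"n_complete":[6,7],"n_incomplete":[4,3],"p":5,"p_inc":3,"y":{"1":[2.182086704907034,1.843001607703789,1.67004527098387,1.090634227320569,3.07538433794277],"2":[0.8058862270989455,0.06958391973142466,1.76046025170147,0.1003465071356795,-0.5042309396699403],"3":[0.5020206678065888,-0.7772794787066895,-0.373113767219017,0.6604156221243731,1.64714860116617],"4":[1.929552026101042,4.02727277011898,2.266954728313809,1.612928523565769,3.207921693092104],"5":[1.249424500454895,2.408604224245972,2.287829594635775,2.813749622214591,2.278989360867661],"6":[1.158259596100836,3.840705331719131,3.363884814603498,3.168051003657324,3.737156477822603],"7":[1.035338454111923,0.9920874944753982,-1.025911325295602,-1.104469169310942,1.007820437656658],"8":[-1.100240831429177,-2.266996747207307,-1.716370567418654,-2.911235456314572,-1.900924303626961],"9":[0.7480160942932591,0.03638395221389082,0.04529772969630111,0.6985892262485194,0.6971808901611394],"10":[1.724764140523097,1.437075592913495,2.376463255663404,2.414247757006332,2.190323489451128],"11":[1.429797772375695,1.579725273155628,1.577380872589436,2.703088318447445,1.476253652598682],"12":[1.629912148396209,3.709938554127127,2.594134436273438,3.099238613541247,2.418524480721479],"13":[-1.641667311595303,-2.067606531291839,-4.34718672887777,-1.653129669584005,-3.24793279389092],"14":[3.340696974418144,3.349524671891712,4.050328227092861],"15":[1.122391411859152,0.9619623434919946,2.012712345416659],"16":[1.746062797428254,3.278588097409477,1.907327486578294],"17":[2.316936610942821,3.099591624810668,3.732329886081527],"18":[0.9121729062726162,-1.362108428146164,-0.3231012137215568],"19":[1.188954705186011,-0.5415046147901037,-0.3813277640997322],"20":[1.086936969509325,0.5352200437502757,1.389877532401333]},"kr_ddf":17.99014000259829,"kr_F":7.489743912653079,"kr_p":0.01355475659912797,"kr_scaling":1,"reml_vb":1.873170547546196,"reml_ve":0.6711699103333589},{"seed":505,"n_complete":[10,10],"n_incomplete":[5,5],"p":3,"p_inc":2,"y":{"1":[-2.403246418082195,-3.160531919947678,-2.058921822111756],"2":[-0.9230053948231184,-1.420528585239444,-0.369399536956317],"3":[0.1324430558656706,-1.642179558649167,0.3190541976658564],"4":[-0.6795525205707832,0.001421846365383339,-0.1216847931177004],"5":[1.796888863127545,1.257949047365699,-0.4063876115125816],"6":[-2.456074187411464,-1.026891778621316,-1.558878795793709],"7":[1.586359107227737,0.6019019563122423,1.205071504807667],"8":[1.602701373269757,-0.8813080620313477,1.779849606809676],"9":[-0.5043338644270384,1.018951214766854,-1.114199941346342],"10":[0.08795586339093986,-0.170700522923467,1.379465150719337],"11":[-1.642413939215991,0.3591615429473205,-0.8904032475530332],"12":[-1.281682236876709,-1.725966826739869,-2.333122820782367],"13":[-0.02003334265360757,-2.564039072673424,-1.484704601013634],"14":[-2.540492754402144,-2.170389409904559,-4.385016973383475],"15":[0.591964076514863,-0.269234625327324,0.04374771401752148],"16":[2.820809368192486,3.635942077588338,2.059141678437439],"17":[0.4671132859310745,1.395947101242618,1.049655860778604],"18":[0.8511699275044418,1.689582129262259,-0.5351077112568853],"19":[0.5886801926276491,3.473247353785991,-0.7784119884395369],"20":[-1.987867529187942,0.1530052593680165,0.8261136953782464],"21":[1.027384072855065,-1.796509801702824],"22":[-0.3633882771846708,-0.6894572765349548],"23":[0.1024495817979663,-1.03554178671785],"24":[-2.000295628362271,-0.127293781095263],"25":[-0.5017181772040659,0.3599606720396198],"26":[-1.386197308851312,-1.719909571752718],"27":[0.365994897023971,1.318265139058988],"28":[-1.473467512699203,-0.6203038827240691],"29":[-3.60626105960734,0.04098752293741939],"30":[0.3684309022843675,0.240830221406443]},"kr_ddf":27.91039701198161,"kr_F":0.005975474025757384,"kr_p":0.9389354454145156,"kr_scaling":1,"reml_vb":1.228451986177849,"reml_ve":1.137189588104949}]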