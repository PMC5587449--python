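species,clade,n,srz_lower,stz_lower,stz_upper,srz_upper,stabilized,outgroup
Pteronotus parnellii,outgroup,1273,0.7,18.8,28.6,35,True,True
Glossophaga longirostris,Glossophagines,202,12.2,21.9,30.7,32.7,False,False
Glossophaga leachii,Glossophagines,270,4.8,15.3,30,34.2,True,False
Glossophaga morenoi,Glossophagines,175,4.5,16.5,29.3,34.6,True,False
Glossophaga commissarisi,Glossophagines,401,5.8,16.9,29.2,34.2,True,False
Glossophaga soricina,Glossophagines,2404,0.6,17.5,28.6,35,True,False
Leptonycteris curasoae,Glossophagines,20,16.6,22.4,30.4,32.6,False,False
Leptonycteris nivalis,Glossophagines,129,0.9,8.5,24.6,33.8,False,False
Leptonycteris yerbabuenae,Glossophagines,403,0,11.5,27.3,34.6,True,False
Monophyllus plethodon,Glossophagines,52,12.8,19.2,27.1,28.9,True,False
Monophyllus redmani,Glossophagines,113,2.6,18.3,28.7,30.4,True,False
Phyllonycteris poeyi,Glossophagines,25,9.8,17.5,29.7,29.8,True,False
Erophylla sezekorni,Glossophagines,87,7.8,17.7,28.1,31,False,False
Brachyphylla nana,Glossophagines,36,9.8,17.2,27.8,30,False,False
Musonycteris harrisoni,Choeronycterines,20,11.4,16,31.4,33.6,False,False
Choeronycteris mexicana,Choeronycterines,285,0,6.3,23.5,32.2,True,False
Choeroniscus godmani,Choeronycterines,96,5.3,19.3,30.1,32.9,True,False
Choeroniscus minor,Choeronycterines,41,8.5,20.6,30,31.2,False,False
Hylonycteris underwoodi,Choeronycterines,98,0,13.7,25.8,32.4,False,False
Lichonycteris obscura,Choeronycterines,28,11.9,21.3,28.7,32,False,False
Anoura latidens,Choeronycterines,23,7.9,20.4,29.2,31.4,False,False
Anoura geoffroyi,Choeronycterines,691,0,10.7,24.6,33.6,True,False
Anoura caudifer,Choeronycterines,217,0.4,15.1,26.5,32.6,True,False
Anoura cultrata,Choeronycterines,43,0,16.5,27.7,30.1,True,False
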