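name,formula,class,rt_min,rt_window_min,deuterium_count
Propanoic acid,C3H6O2,SCFA,2.5,0.5,0
Butyric acid,C4H8O2,SCFA,5.1,0.5,0
Glyco-a/b-muricholic acid,C26H43NO6,glycine-conjugated bile acid,7.3,0.5,0
w-Muricholic acid,C24H40O5,unconjugated bile acid,8.7,0.5,0
a-Muricholic acid,C24H40O5,unconjugated bile acid,9.1,0.5,0
b-Muricholic acid,C24H40O5,unconjugated bile acid,9.4,0.5,0
Glycohyocholic acid,C26H43NO6,glycine-conjugated bile acid,9.4,0.5,0
Glycoursodeoxycholic acid,C26H43NO5,glycine-conjugated bile acid,11.1,0.5,0
Glycohyodeoxycholic acid,C26H43NO5,glycine-conjugated bile acid,11.1,0.5,0
Glycocholic acid,C26H43NO6,glycine-conjugated bile acid,11.3,0.5,0
Hyocholic acid,C24H40O5,unconjugated bile acid,11.5,0.5,0
Indole-3-acetic acid,C10H9NO2,indole,11.6,0.5,0
Ursodeoxycholic acid,C24H40O4,unconjugated bile acid,12.1,0.5,0
Cholic acid,C24H40O5,unconjugated bile acid,12.5,0.5,0
Hyodeoxycholic acid,C24H40O4,unconjugated bile acid,12.6,0.5,0
Glycochenodeoxycholic acid,C26H43NO5,glycine-conjugated bile acid,14.1,0.5,0
Glycodeoxycholic acid,C26H43NO5,glycine-conjugated bile acid,14.1,0.5,0
Chenodeoxycholic acid,C24H40O4,unconjugated bile acid,14.1,0.5,0
Deoxycholic acid,C24H40O4,unconjugated bile acid,14.8,0.5,0
Glycolithocholic acid,C26H43NO4,glycine-conjugated bile acid,15.3,0.5,0
Lithocholic acid,C24H40O3,unconjugated bile acid,16.0,0.5,0
Lauric acid,C12H24O2,saturated FA,18.6,0.5,0
Stearidonic acid,C18H28O2,n-3 PUFA,19.9,0.5,0
Eicosapentaenoic acid,C20H30O2,n-3 PUFA,21.1,0.5,0
a-Linolenic acid,C18H30O2,n-3 PUFA,21.2,0.5,0
Myristic acid,C14H28O2,saturated FA,21.3,0.5,0
g-Linolenic acid,C18H30O2,n-6 PUFA,21.5,0.5,0
Palmitoleic acid,C16H30O2,monounsaturated FA,22.0,0.5,0
Docosahexaenoic acid,C22H32O2,n-3 PUFA,22.5,0.5,0
Arachidonic acid,C20H32O2,n-6 PUFA,22.8,0.5,0
Linoleic acid,C18H32O2,n-6 PUFA,22.9,0.5,0
Docosapentaenoic acid,C22H34O2,n-3 PUFA,23.3,0.5,0
Dihomo-g-linolenic acid,C20H34O2,n-6 PUFA,24.0,0.5,0
Palmitic acid,C16H32O2,saturated FA,24.4,0.5,0
Adrenic acid,C22H36O2,n-6 PUFA,25.0,0.5,0
Oleic acid,C18H34O2,monounsaturated FA,25.1,0.5,0
Stearic acid,C18H36O2,saturated FA,27.6,0.5,0
Arachidic acid,C20H40O2,saturated FA,29.6,0.5,0
Nervonic acid,C24H46O2,monounsaturated FA,30.3,0.5,0
Lignoceric acid,C24H48O2,saturated FA,31.1,0.5,0
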