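state,name,N,S_obs,a,b,S_exp,C
Chiapas,Arriaga Tonalá,2162,337,88,53,407.86,0.83
Chiapas,Comitán,3821,422,79,62,470.9,0.89
Chiapas,El Triunfo,4884,396,41,34,419.4,0.95
Chiapas,Tuxtla Gutiérrez,4058,463,93,54,540.8,0.86
Ciudad de México,Valle de México,6818,349,71,28,434.7,0.80
Guerrero,Chilpancingo / Omiltemi,15230,380,51,24,431.0,0.88
Michoacán,Patzcuaro / Morelia / Lagos de Michoacán,2144,269,60,26,334.5,0.80
Michoacán,Tancítaro / Uruapan,1396,253,50,28,295.2,0.86
Nayarit,Tepic / San Blas,5079,405,66,34,466.3,0.87
Oaxaca,Matías Romero to north,3994,404,84,42,485.0,0.83
Oaxaca,Miahuatlán / Mixtepec,1054,205,54,34,245.9,0.83
Oaxaca,Tapanatepec / Zanatepec / Cerro El Baúl,4752,355,63,28,422.3,0.84
Quintana Roo,Isla Cozumel,2159,216,39,46,231.8,0.93
Sinaloa,Durango Hwy / Espinazo del Diablo,3857,293,57,24,356.8,0.82
Sinaloa,Rosario,1912,247,55,35,288.2,0.86
Sonora,Álamos,3403,273,42,23,308.9,0.88
Veracruz,Los Tuxtlas,10499,457,78,41,528.5,0.87
Veracruz,Orizaba / Córdoba,2741,402,94,52,484.4,0.83
Veracruz,Xalapa,2135,303,54,49,331.6,0.91
Yucatán,Chichén-Itzá,2612,220,37,20,251.7,0.87
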