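state,name,latitude,longitude,N,S_obs,a,b,S_exp,C
Baja California,Isla Cedros,28.208,-115.244,213,45,12,10,51.0,0.88
Baja California,Isla San Benito,28.308,-115.594,398,60,19,11,74.2,0.81
Baja California Sur,El Triunfo 2,23.808,-110.094,267,56,15,9,66.5,0.84
Baja California Sur,La Paz 2,24.158,-110.244,1167,137,35,34,154.0,0.89
Baja California Sur,Laguna San Ignacio 2,27.308,-112.894,339,55,17,11,66.3,0.83
Baja California Sur,San Jose de Cabo,23.058,-109.694,1339,174,47,25,215.5,0.81
Baja California Sur,Sierra de la Laguna,23.458,-109.794,314,56,9,5,62.0,0.90
Baja California Sur,Sierra de la Laguna 4,23.558,-109.944,813,55,14,6,68.0,0.81
Chiapas,El Fénix,16.658,-93.994,258,68,14,12,75.0,0.91
Chiapas,Escuintla / Finca La Esperanza,15.358,-92.644,1362,229,45,31,259.9,0.88
Chiapas,Laguna Ocotal,16.808,-91.444,531,125,21,30,131.8,0.95
Chiapas,Pueblo Nuevo,17.158,-92.894,480,133,39,28,158.5,0.84
Chiapas,San Cristóbal de las Casas,16.658,-92.594,339,69,17,11,80.3,0.86
Chiapas,San Cristóbal de las Casas 3,16.708,-92.694,342,65,18,11,77.7,0.84
Chihuahua,Arroyo del Alamo,29.458,-106.794,214,76,21,17,87.6,0.87
Chihuahua,Arroyo el Mesteo,29.408,-106.894,208,76,22,21,86.4,0.88
Chihuahua,Colonia Pacheco,28.658,-106.194,283,63,17,9,76.6,0.82
Chihuahua,Colonia Pacheco 2,30.108,-108.294,945,103,21,9,124.0,0.83
Chihuahua,Rancho Pinos Altos,28.258,-108.294,259,49,8,5,53.6,0.91
Chihuahua,Rio El Gavilan,30.008,-108.394,325,83,19,15,93.7,0.89
Ciudad de México,Xochimilco,19.258,-99.094,229,83,30,21,102.7,0.81
Coahuila,Sabinas,27.858,-101.144,625,114,28,17,135.0,0.84
Colima,Cihuatlan,19.208,-104.544,354,89,24,15,106.2,0.84
Durango,El Salto,23.758,-105.544,205,55,12,16,58.9,0.93
Durango,Neveros,23.758,-105.744,264,65,16,15,72.5,0.90
Durango,Nievero,24.008,-104.744,215,52,12,12,57.1,0.91
Durango,Santa Gertrudis,23.558,-104.394,254,86,27,17,105.4,0.82
Durango,Santa Teresa,22.608,-104.844,264,68,16,10,78.9,0.86
Durango,Tamazula,24.958,-106.944,225,99,37,29,121.1,0.82
Guanajuato,Rancho Enmedio,21.108,-101.194,401,82,22,14,97.4,0.84
Guerrero,Acahuizotla 2,17.358,-99.394,476,129,41,26,159.3,0.81
Guerrero,Ajuchitlán,18.158,-100.494,219,40,9,4,47.2,0.85
Guerrero,Chilpancingo,17.558,-99.494,6530,270,50,22,323.3,0.84
Guerrero,Cuapongo,17.508,-99.644,1443,169,48,30,205.4,0.82
Guerrero,Omiltemi 2,17.558,-99.644,2419,206,47,30,240.9,0.86
Guerrero,Teotepec,17.458,-100.194,254,47,10,6,53.4,0.88
Jalisco,Atoyac,20.008,-103.594,316,107,31,24,125.5,0.85
Jalisco,Atoyac 2,20.008,-103.544,223,72,20,15,83.8,0.86
Jalisco,Lagos de Moreno 2,21.508,-101.694,202,70,24,15,87.2,0.80
Jalisco,Tapalpa,19.958,-103.744,288,102,34,22,126.3,0.81
Michoacán,Apatzingan,19.158,-102.444,244,68,18,12,79.7,0.85
Michoacán,Pátzcuaro,19.458,-101.594,361,111,35,23,135.7,0.82
Michoacán,Rancho El Bonete,18.958,-101.894,297,95,30,20,115.6,0.82
Michoacán,Tzitzio,19.608,-100.944,285,78,19,13,90.2,0.87
Michoacán,Tzitzio 2,19.658,-100.894,299,97,32,22,118.5,0.82
Michoacán,Uruapan,19.408,-101.994,391,94,26,14,115.6,0.81
Michoacán,Zacapu,19.808,-101.794,475,126,34,30,144.1,0.87
Morelos,Cuernavaca,18.908,-99.244,541,159,50,32,196.1,0.81
México,East of Zitácuaro,19.408,-100.194,250,77,22,14,92.3,0.83
México,Puerto Lengua de Vaca,19.258,-99.894,224,63,14,14,69.0,0.91
México,Temascaltepec,19.058,-100.044,632,128,29,21,146.4,0.87
Nayarit,Islas Tres Marías,21.458,-106.444,394,64,15,15,70.5,0.91
Nayarit,Islas Tres Marías 3,21.458,-106.394,475,68,20,12,82.6,0.82
Nayarit,San Blas 3,21.558,-105.294,701,235,75,50,289.3,0.81
Nayarit,Sauta,21.708,-105.144,370,107,34,20,133.6,0.80
Nayarit,Tepic,21.258,-104.644,207,69,18,20,76.3,0.90
Nayarit,Tepic 2,21.508,-104.894,1126,178,43,22,217.2,0.82
Oaxaca,Cerro San Felipe,17.158,-96.694,236,66,16,10,76.9,0.86
Oaxaca,Chivela,16.708,-94.994,251,73,20,16,84.1,0.87
Oaxaca,Palomares,17.108,-95.044,782,213,67,44,262.1,0.81
Oaxaca,Rancho San Carlos,17.208,-94.944,340,127,42,28,156.6,0.81
Oaxaca,Rio Molino,16.058,-96.444,374,84,17,16,92.0,0.91
Oaxaca,Totontepec,17.258,-96.044,533,107,15,30,110.4,0.97
Quintana Roo,Felipe Carrillo Puerto,19.558,-88.044,212,86,26,31,96.1,0.89
Quintana Roo,Felipe Carrillo Puerto 2,19.608,-88.044,342,131,45,37,157.0,0.83
Quintana Roo,Isla Cozumel 4,20.508,-86.944,650,154,17,49,156.7,0.98
Sinaloa,Babizos,25.758,-107.444,472,81,20,10,98.2,0.82
Sinaloa,Rancho Liebre,23.558,-105.844,601,126,26,21,140.7,0.90
Sonora,Babizos 2,27.008,-108.394,539,106,29,18,127.3,0.83
Sonora,Chinobampo,26.958,-109.294,215,74,22,22,84.0,0.88
Sonora,Hacienda de San Rafael,27.108,-108.694,220,61,18,14,71.2,0.86
Sonora,Huasa,28.608,-109.794,221,66,21,12,82.1,0.80
Sonora,La Chumata,29.908,-110.594,241,68,15,17,73.8,0.92
Sonora,Oposura,29.808,-109.694,494,124,27,24,138.0,0.90
Sonora,Rancho Guirocoba 2,26.958,-108.694,879,168,39,27,194.4,0.86
Sonora,Tecoripa,28.608,-109.944,242,75,21,18,86.0,0.87
Tamaulipas,Above Ciudad Victoria,23.708,-99.244,202,75,2,49,75.0,1.00
Tamaulipas,Ciudad Victoria,23.708,-99.144,370,177,52,33,215.9,0.82
Tamaulipas,Gomez Farías 3,23.058,-99.094,354,123,44,32,151.6,0.81
Tamaulipas,Matamoros,25.858,-97.494,628,207,60,42,248.1,0.83
Tamaulipas,Tampico,22.258,-97.844,1038,211,47,41,236.7,0.89
Veracruz,Balzapote 4,18.608,-95.044,3491,286,56,43,321.0,0.89
Veracruz,Cerro Guzman,19.208,-96.394,542,141,43,29,171.0,0.82
Veracruz,Coatepec,19.458,-96.944,377,122,16,49,124.4,0.98
Veracruz,Coyame,18.408,-94.994,338,129,30,41,139.3,0.93
Veracruz,Huatusco,19.158,-96.944,282,95,26,30,105.4,0.90
Veracruz,Lago de Catemaco,18.408,-95.144,205,79,28,21,96.1,0.82
Veracruz,Misantla,19.908,-96.844,307,108,3,62,108.0,1.00
Veracruz,Perote,19.558,-97.244,263,88,14,44,90.0,0.98
Veracruz,Presidio 2,18.658,-96.744,1000,219,54,36,257.6,0.85
Veracruz,Rancho Caracol 3,18.458,-96.644,358,127,41,26,157.3,0.81
Veracruz,Xalapa,19.558,-96.944,887,192,34,54,202.2,0.95
Yucatán,Chichén-Itzá,20.658,-88.594,1727,193,26,23,206.5,0.93
Yucatán,Mérida,20.958,-89.644,242,118,38,25,144.9,0.81
Yucatán,Xocompich,20.758,-88.544,270,115,44,40,138.0,0.83
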