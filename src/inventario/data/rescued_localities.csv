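state,name,latitude,longitude,N,S_obs,a,b,S_exp,C
Nuevo León,Monterrey,25.687,-100.316,418,145,52,38,178.9,0.81
Tabasco,1 mi E Teapa,17.563,-92.948,361,158,57,41,195.9,0.81
San Luis Potosí,[Ciudad] Valles,21.997,-99.011,227,93,34,26,113.7,0.82
Chiapas,26 km N by road Ocozocuautla,16.995,-93.379,400,145,55,40,181.1,0.80
Oaxaca,1 mi SW Valle Nacional,17.757,-96.320,485,169,54,46,199.4,0.85
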