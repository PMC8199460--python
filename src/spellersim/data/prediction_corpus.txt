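# Synthetic word-frequency corpus fixture (word<TAB>count).
# Constructed so the default tasks see the protocol's prediction
# availabilities: "Francisco" after 1 typed character, "experimento"
# after 3, "universidad" after 2, and the e-mail receiver after 2,
# with exactly seven higher-frequency words masking each earlier prefix.
ESTAR	900
ESTE	890
ESO	880
ELLA	870
ENTRE	860
ESTO	850
ERES	840
EXAMEN	830
EXITO	820
EXACTO	810
EXTRA	800
EXCESO	790
EXIGIR	780
EXTERIOR	770
USTED	760
UNO	750
USAR	740
ULTIMO	730
UNA	720
UNIDAD	710
URGENTE	700
RAPIDO	690
ROJO	680
REY	670
RATO	660
REGALO	650
ROPA	640
RAZON	630
Francisco	300
experimento	300
universidad	300
Ricardo	300
HOLA	260
GRACIAS	250
BUENOS	240
DIAS	230
QUE	220
COMIDA	210
FAVORITA	200
MENSAJE	190
TELEFONO	180
AMIGO	170
CASA	160
PASTA	150
FELIZ	140
NAVIDAD	130
PAULA	120
ALVARO	110
MANANA	100
TARDE	90
NOCHE	80
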