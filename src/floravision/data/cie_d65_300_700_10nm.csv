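wavelength_nm,relative_power
300,0.0341
310,3.2945
320,20.2360
330,37.0535
340,39.9488
350,44.9117
360,46.6383
370,52.0891
380,49.9755
390,54.6482
400,82.7549
410,91.4860
420,93.4318
430,86.6823
440,104.8650
450,117.0080
460,117.8120
470,114.8610
480,115.9230
490,108.8110
500,109.3540
510,107.8020
520,104.7900
530,107.6890
540,104.4050
550,104.0460
560,100.0000
570,96.3342
580,95.7880
590,88.6856
600,90.0062
610,89.5991
620,87.6987
630,83.2886
640,83.6992
650,80.0268
660,80.2146
670,82.2778
680,78.2842
690,69.7213
700,71.6091
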