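species,role,spectral_observed,spectral_expected,spectral_unexpected,bee_observed,bee_expected,bee_unexpected,hummingbird_observed,hummingbird_expected,hummingbird_unexpected,chlorophyll_observed,chlorophyll_expected,chlorophyll_unexpected
N. tabacum 095-55,polyploid,R,W|P,1,UV-B,B-G,1,sUV-P,W|P,1,N,C,1
N. tabacum 51789,polyploid,P,W|P,0,B-G,B-G,0,P,W|P,0,N,C,1
N. tabacum Chulumani,polyploid,W,W|P,0,B-G,B-G,0,P,W|P,0,N,C,1
syn N. tabacum QM,polyploid,P,W|P,0,B,B-G,1,LP,W|P,1,N,C,1
syn N. tabacum TH37,polyploid,P,W|P,0,B-G,B-G,0,P,W|P,0,N,C,1
TH32,polyploid,P,W|P,0,B-G,B-G,0,P,W|P,0,N,C,1
N. rustica var. asiatica,polyploid,G,G,0,LG,G|B-G,1,G,G|W,0,C,C,0
N. rustica var. pavonii,polyploid,G,G,0,G,G|B-G,0,G,G|W,0,C,C,0
syn U x P,homoploid,G,G,0,UV-G,G|B-G,1,UV-G,G|W,1,C,C,0
syn F1,homoploid,G,G,0,LG,G|B-G,1,G,G|W,0,C,C,0
syn N. rustica S0,polyploid,G,G,0,LG,G|B-G,1,G,G|W,0,C,C,0
syn N. rustica S1,polyploid,G,G,0,LG,G|B-G,1,G,G|W,0,C,C,0
N. arentsii,polyploid,W,G|W,0,B-G,B-G,0,P,W,1,C,C,0
N. clevelandii,polyploid,W,UV-W|W,0,B-G,UV|B-G,0,P,UV-W|W,1,N,C,1
N. quadrivalvis TW18,polyploid,W,UV-W|W,0,B-G,UV|B-G,0,W,UV-W|W,0,C,C,0
N. quadrivalvis 9047,polyploid,W,UV-W|W,0,B-G,UV|B-G,0,W,UV-W|W,0,C,C,0
N. x obtusiata line 1,polyploid,W,UV-W|W,0,B-G,UV|B-G,0,W,UV-W|W,0,C,C,0
N. x obtusiata line 2,polyploid,W,UV-W|W,0,B-G,UV|B-G,0,W,UV-W|W,0,C,C,0
N. x obtusiata line 5,polyploid,W,UV-W|W,0,B-G,UV|B-G,0,W,UV-W|W,0,C,C,0
N. repanda,polyploid,W,W|UV-W,0,B-G,B-G|UV,0,W,W|UV-W,0,N,C,1
N. nesophila,polyploid,W,W|UV-W,0,B-G,B-G|UV,0,W,W|UV-W,0,N,C,1
N. stocktonii,polyploid,W,W|UV-W,0,B-G,B-G|UV,0,W,W|UV-W,0,C,C,0
N. nudicaulis,polyploid,UV-W,W|UV-W,0,UV,B-G|UV,0,UV-W,W|UV-W,0,C,C,0
N. benthamiana,polyploid,W,W,0,,,,,,,N,C,1
N. forsteri,polyploid,W,W,0,,,,,,,C,C,0
N. gossei,polyploid,W,W,0,,,,,,,N,C,1
N. megalosiphon,polyploid,W,W,0,,,,,,,N,C,1
N. occidentalis,polyploid,W,W,0,,,,,,,N,C,1
N. suaveolens,polyploid,W,W,0,,,,,,,N,C,1
N. glauca 51725,homoploid,Y,W,1,,,,,,,C,C,0
N. glauca 51751,homoploid,Y|G,W,1,,,,,,,C,C,0
N. linearis TW77,homoploid,UV-W,W,1,,,,,,,C,C,0
N. linearis 9647,homoploid,UV-W,W,1,,,,,,,C,C,0
N. glutinosa,homoploid,P,P|W|G,0,,,,,,,C,C,0
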