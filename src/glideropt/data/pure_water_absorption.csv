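# Pure water absorption coefficient a_w (m^-1).
# Source: Pope & Fry (1997), Appl. Opt. 36, 8710-8723, integrating-cavity
# measurements; values transcribed onto a 10 nm grid. Long-wave end
# (>= 730 nm) after Smith & Baker (1981).
# Columns: wavelength_nm, a_w_m1
wavelength_nm,a_w_m1
380,0.01137
390,0.00941
400,0.00663
410,0.00473
420,0.00454
430,0.00495
440,0.00635
450,0.00922
460,0.00979
470,0.01060
480,0.01270
490,0.01500
500,0.02040
510,0.03250
520,0.04090
530,0.04340
540,0.04740
550,0.05650
560,0.06190
570,0.06950
580,0.08960
590,0.13510
600,0.22240
610,0.26440
620,0.27550
630,0.29160
640,0.31080
650,0.34000
660,0.41000
670,0.43900
680,0.46500
690,0.51600
700,0.62400
710,0.82700
720,1.23100
730,1.79900
740,2.38000
750,2.47000
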