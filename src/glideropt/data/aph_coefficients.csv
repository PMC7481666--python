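# Phytoplankton absorption power-law coefficients:
#   a_ph(lambda, Chl) = A_ph(lambda) * Chl^(1 + B_ph(lambda))
# After Bricaud et al. (1998), JGR 103, 31033-31044 (global Case-1 fit,
# a_ph = A * Chl^E with E = 1 + B_ph), transcribed at the nine model
# wavelengths; 715 nm entry extrapolated (pigment absorption negligible).
# Columns: wavelength_nm, A_ph, B_ph
wavelength_nm,A_ph,B_ph
412,0.0558,-0.236
440,0.0654,-0.272
488,0.0430,-0.313
510,0.0292,-0.320
532,0.0192,-0.311
555,0.0124,-0.268
650,0.0089,-0.151
676,0.0232,-0.107
715,0.0010,-0.100
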