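# Particulate backscattering power-law coefficients:
#   b_bp(lambda, Chl) = A_bb(lambda) * Chl^B_bb(lambda)
# Regression coefficients with 95% confidence intervals (A CI is a
# multiplicative factor from the log-space fit; B CI is additive) and
# coefficient of determination. No 412 nm entry: that channel was excluded
# for data-quality reasons. The 700 nm row is extrapolated/interpolated.
# Columns: wavelength_nm, A_bb, A_ci_factor, B_bb, B_ci, r2
wavelength_nm,A_bb,A_ci_factor,B_bb,B_ci,r2
440,0.002,1.312,0.315,0.121,0.9243
488,0.001,1.555,0.766,0.198,0.9656
510,0.001,1.237,0.589,0.095,0.9865
532,0.001,1.366,0.623,0.140,0.9740
555,0.001,1.290,0.624,0.114,0.9827
650,0.001,1.128,0.568,0.054,0.9953
676,0.001,1.569,0.659,0.202,0.9519
700,0.001,1.313,0.683,0.122,0.9835
715,0.001,1.178,0.703,0.073,0.9835
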