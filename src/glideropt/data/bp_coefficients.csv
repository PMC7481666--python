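# Particulate scattering power-law coefficients:
#   b_p(lambda, Chl) = A_b(lambda) * Chl^B_b(lambda)
# Regression coefficients with 95% confidence intervals (A CI is a
# multiplicative factor from the log-space fit; B CI is additive) and
# coefficient of determination.
# Columns: wavelength_nm, A_b, A_ci_factor, B_b, B_ci, r2
wavelength_nm,A_b,A_ci_factor,B_b,B_ci,r2
412,0.133,1.768,0.785,0.255,0.9457
440,0.126,2.044,0.844,0.320,0.9265
488,0.169,1.449,0.849,0.166,0.9802
510,0.165,1.451,0.851,0.167,0.9801
532,0.203,1.365,0.834,0.139,0.9855
555,0.219,1.326,0.829,0.126,0.9879
650,0.210,1.507,0.903,0.184,0.9786
676,0.152,2.311,0.886,0.375,0.9089
715,0.213,1.685,0.925,0.233,0.9671
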