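# Pure-seawater scattering parameterization (Morel 1974-type power law):
#   b_w(lambda, S, T) = b_ref * (lambda_ref / lambda)^exponent
#                       * (1 + salinity_gain * S / salinity_ref)
#                       * (1 + temp_gain_per_degC * (T - temp_ref_degC))
# b_ref is the pure-water (S = 0) value at lambda_ref; dissolved sea salt
# raises molecular scattering by ~30% at oceanic salinity (Morel 1974);
# temperature sensitivity is weak and positive (cf. Zhang et al. 2009).
# Backscattering is b_w / 2 (symmetric molecular phase function).
# Columns: parameter, value
parameter,value
lambda_ref_nm,450.0
b_ref_m1,0.00345
exponent,4.32
salinity_gain,0.30
salinity_ref_psu,37.0
temp_gain_per_degC,0.0003
temp_ref_degC,20.0
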