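# glideropt

Convert standard glider sensor outputs — salinity from the CTD plus
chlorophyll fluorescence, CDOM fluorescence and 700 nm particulate
backscattering from an optical triplet sensor — into spectral bulk
inherent optical properties (absorption, scattering, backscattering)
and remote-sensing reflectance, so autonomous-platform observations can
be compared quantitatively with satellite ocean-colour data.

## What it does

- **Water optics** (`glideropt.water`): pure-water absorption from an
  embedded literature table and pure-seawater molecular scattering with
  explicit salinity/temperature dependence (`bb_w = b_w / 2`).
- **Forward bio-optical model** (`glideropt.model`): per-wavelength
  power laws in chlorophyll for phytoplankton absorption, particulate
  scattering and backscattering; exponential spectral shapes anchored at
  440 nm for non-algal particle and CDOM absorption (CDOM anchored to
  salinity, valid 27–35 PSU with a constant fallback outside); bulk
  IOPs as sums of the partial components.
- **Glider pipeline** (`glideropt.glider`): profile separation of the
  sawtooth record, per-profile median/MAD despiking, a hybrid
  chlorophyll estimator (fluorescence up to 2 mg m⁻³, backscattering
  inversion above — immune to surface fluorescence quenching), Barnes
  successive-correction gridding onto a 2 km × 5 m raster, and cell-wise
  IOP transects.
- **Reflectance** (`glideropt.reflectance`): a simplified Rrs forward
  model, `Rrs = (f/Q)(bb/a)(1 − r_F)/n_w²` with f/Q = 0.0922, and a
  band-matched statistical comparison of glider vs satellite Rrs
  ensembles (means, SD, 95% CI, 1.5×IQR outliers, mean percent error).
- **Synthetic data** (`glideropt.synth`): polar-front transect
  scenarios (temperature/salinity drop and a surface-intensified bloom
  north of ~75.8° N), sawtooth glider sampling with lognormal sensor
  noise, daytime quenching emulation and injected spikes, and satellite
  Rrs ensembles — everything needed to test the pipeline end to end
  with no external data.

## CLI

```sh
# evaluate the forward model
glideropt model --chl 1.0 --salinity 34.0 --out spectrum.csv

# generate a synthetic deployment
glideropt synth --out glider.csv --truth-out truth.csv --seed 1

# full pipeline: despike -> profiles -> hybrid Chl -> Barnes grid ->
# IOP transect -> per-column surface Rrs (-> satellite comparison)
glideropt run glider.csv --outdir out/
glideropt run glider.csv --satellite sat_rrs.csv --outdir out/

# individual stages
glideropt grid glider.csv --out transect.nc --spacing 2,5 --radii 10,10
glideropt rrs transect.nc --out rrs.csv
glideropt compare rrs.csv sat_rrs.csv --out cmp
```

Glider input is CSV (or NetCDF) with columns `time, lat, lon, depth_m,
temp_C, sal_psu, chl_fl_mg_m3, cdom_fl, bbp700_m1`; satellite Rrs input
is a long-format CSV with `spectrum_id, band_nm, rrs_sr_1`. Pipeline
constants live in a YAML config (`glideropt run --config config.yaml`);
defaults reproduce the model's published constants.

## Coefficient provenance

All empirical tables ship as plain-text CSVs under
`src/glideropt/data/` with citation headers: pure-water absorption
(Pope & Fry-type), a Morel-type seawater scattering parameterization,
chlorophyll-specific phytoplankton absorption coefficients (after
Bricaud et al.), and the regional scattering/backscattering power-law
tables with their 95% confidence intervals. Backscattering has no
412 nm entry (channel excluded for data quality); the 700 nm row is
extrapolated/interpolated and drives the backscattering-to-chlorophyll
inversion.
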