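"""Remote-sensing reflectance forward model and ensemble comparison.

A simplified reflectance model (no Raman scattering, no bidirectional
effects) maps surface absorption and backscattering to above-water
remote-sensing reflectance; glider- and satellite-derived Rrs ensembles
are then compared band-by-band with distributional statistics.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .coefficients import DEFAULT, ModelCoefficients

__all__ = [
    "RrsSpectrum",
    "ComparisonSummary",
    "rrs_from_iops",
    "surface_average",
    "glider_rrs",
    "band_match",
    "compare_ensembles",
]


@dataclass
class RrsSpectrum:
    """One remote-sensing reflectance spectrum (sr^-1)."""

    wavelengths: np.ndarray
    rrs: np.ndarray
    provenance: str = "glider"  # "glider" | "satellite"

    def __post_init__(self):
        self.wavelengths = np.atleast_1d(np.asarray(self.wavelengths, float))
        self.rrs = np.atleast_1d(np.asarray(self.rrs, float))
        if self.wavelengths.shape != self.rrs.shape:
            raise ValueError("wavelengths and rrs must have equal length")
        if np.any(self.rrs[np.isfinite(self.rrs)] < 0):
            raise ValueError("negative remote-sensing reflectance")


@dataclass
class ComparisonSummary:
    """Per-band distributional statistics of two Rrs ensembles."""

    bands: pd.DataFrame  # one row per matched band pair
    mean_error: float  # percent

    def to_json_dict(self) -> dict:
        return {
            "mean_error_percent": self.mean_error,
            "bands": self.bands.to_dict(orient="records"),
        }


def rrs_from_iops(a, bb, coeffs: ModelCoefficients = DEFAULT):
    """Remote-sensing reflectance from bulk absorption and backscattering.

    ``Rrs = (f/Q) * (bb/a) * (1 - r_F) / n_w**2`` with f/Q = 0.0922,
    Fresnel reflectance r_F = 0.021 and water refractive index 1.34.
    """
    a = np.asarray(a, dtype=float)
    bb = np.asarray(bb, dtype=float)
    if np.any(a[np.isfinite(a)] <= 0):
        raise ValueError("absorption must be > 0")
    if np.any(bb[np.isfinite(bb)] < 0):
        raise ValueError("backscattering must be >= 0")
    out = coeffs.fq_ratio * (bb / a) * (1.0 - coeffs.fresnel_r) / coeffs.n_water**2
    return float(out) if np.ndim(out) == 0 else out


def surface_average(
    transect: xr.Dataset, field_name: str, depth_limit: float = 2.0
) -> xr.DataArray:
    """Per-column mean of a field over cells with centre depth <= limit.

    If no cell centre lies within the limit (e.g. a 5 m grid whose first
    centre is at 2.5 m), the shallowest grid cell is used instead, as
    the closest gridded analogue of a near-surface average.
    """
    if field_name not in transect:
        raise KeyError(f"unknown field {field_name!r}")
    da = transect[field_name]
    depth = transect["depth_m"]
    sel = depth <= depth_limit
    if not bool(sel.any()):
        sel = depth == float(depth.min())
    return da.where(sel).mean("depth_m", skipna=True)


def glider_rrs(
    transect: xr.Dataset,
    wavelengths=None,
    depth_limit: float = 2.0,
    coeffs: ModelCoefficients = DEFAULT,
) -> list[RrsSpectrum]:
    """Per-column Rrs spectra from surface-averaged modelled a and bb.

    ``transect`` must already carry ``a_total`` and ``bb_total`` fields
    (see :func:`glideropt.glider.transect_iops`).  Columns whose surface
    cells are all missing are skipped.
    """
    if "a_total" not in transect or "bb_total" not in transect:
        raise ValueError("transect lacks IOP fields; run transect_iops first")
    a_surf = surface_average(transect, "a_total", depth_limit)
    bb_surf = surface_average(transect, "bb_total", depth_limit)
    lam = np.asarray(
        transect["wavelength_nm"].values if wavelengths is None else wavelengths,
        dtype=float,
    )
    if wavelengths is not None:
        a_surf = a_surf.sel(wavelength_nm=lam)
        bb_surf = bb_surf.sel(wavelength_nm=lam)

    spectra = []
    for j in range(a_surf.sizes["along_track_km"]):
        a_col = a_surf.isel(along_track_km=j).values
        bb_col = bb_surf.isel(along_track_km=j).values
        if not (np.all(np.isfinite(a_col)) and np.all(np.isfinite(bb_col))):
            continue
        spectra.append(
            RrsSpectrum(lam, rrs_from_iops(a_col, bb_col, coeffs), "glider")
        )
    return spectra


def band_match(
    glider_wavelengths, satellite_wavelengths, tolerance: float = 10.0
) -> list[tuple[float, float]]:
    """Pair each glider band with the nearest satellite band.

    Pairs farther apart than ``tolerance`` nm are dropped (no spectral
    interpolation).
    """
    gw = np.atleast_1d(np.asarray(glider_wavelengths, float))
    sw = np.atleast_1d(np.asarray(satellite_wavelengths, float))
    if gw.size == 0 or sw.size == 0:
        raise ValueError("band lists must be non-empty")
    pairs = []
    for g in gw:
        s = sw[np.argmin(np.abs(sw - g))]
        if abs(s - g) <= tolerance:
            pairs.append((float(g), float(s)))
    return pairs


def _band_values(spectra: list[RrsSpectrum], wavelength: float) -> np.ndarray:
    vals = []
    for sp in spectra:
        idx = np.nonzero(np.isclose(sp.wavelengths, wavelength))[0]
        if idx.size:
            vals.append(sp.rrs[idx[0]])
    return np.asarray(vals, dtype=float)


def _ensemble_stats(values: np.ndarray) -> dict:
    n = values.size
    mean = float(np.mean(values))
    std = float(np.std(values, ddof=1)) if n > 1 else 0.0
    half = 1.96 * std / np.sqrt(n) if n > 1 else 0.0
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    outliers = int(np.sum((values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr)))
    return {
        "mean": mean,
        "std": std,
        "ci_low": mean - half,
        "ci_high": mean + half,
        "n_outliers": outliers,
        "n": n,
    }


def compare_ensembles(
    glider: list[RrsSpectrum],
    satellite: list[RrsSpectrum],
    tolerance: float = 10.0,
) -> ComparisonSummary:
    """Band-matched distributional comparison of two Rrs ensembles.

    Per matched band: ensemble means, standard deviations, 95% CI of the
    mean, and 1.5 x IQR outlier counts.  The scalar ``mean_error`` is
    the mean over matched bands of |mean_glider - mean_sat| / mean_sat,
    in percent.
    """
    if len(glider) < 2 or len(satellite) < 2:
        raise ValueError("need at least two spectra per ensemble")
    g_bands = np.unique(np.concatenate([s.wavelengths for s in glider]))
    s_bands = np.unique(np.concatenate([s.wavelengths for s in satellite]))
    pairs = band_match(g_bands, s_bands, tolerance)
    if not pairs:
        raise ValueError("no matched bands within tolerance")

    rows = []
    errors = []
    for g_lam, s_lam in pairs:
        gv = _band_values(glider, g_lam)
        sv = _band_values(satellite, s_lam)
        if gv.size == 0 or sv.size == 0:
            continue
        gs = _ensemble_stats(gv)
        ss = _ensemble_stats(sv)
        err = abs(gs["mean"] - ss["mean"]) / ss["mean"] * 100.0
        errors.append(err)
        rows.append(
            {
                "glider_band_nm": g_lam,
                "satellite_band_nm": s_lam,
                "glider_mean": gs["mean"],
                "satellite_mean": ss["mean"],
                "glider_std": gs["std"],
                "satellite_std": ss["std"],
                "glider_ci_low": gs["ci_low"],
                "glider_ci_high": gs["ci_high"],
                "satellite_ci_low": ss["ci_low"],
                "satellite_ci_high": ss["ci_high"],
                "glider_outliers": gs["n_outliers"],
                "satellite_outliers": ss["n_outliers"],
                "band_error_percent": err,
            }
        )
    if not rows:
        raise ValueError("no matched bands with data on both sides")
    return ComparisonSummary(
        bands=pd.DataFrame(rows), mean_error=float(np.mean(errors))
    )
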