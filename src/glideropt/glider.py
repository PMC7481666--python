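"""Glider time-series processing.

Turns raw sawtooth glider records into despiked series, individual
dive/climb profiles, hybrid chlorophyll estimates, objectively analysed
(Barnes) transect grids, and finally gridded IOP fields via the forward
model.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .coefficients import DEFAULT, ModelCoefficients
from . import model
from .water import pure_seawater_scattering, pure_water_absorption

__all__ = [
    "GliderProfile",
    "despike",
    "split_profiles",
    "along_track_distance",
    "chl_from_bbp",
    "hybrid_chl",
    "barnes_grid",
    "grid_transect",
    "transect_iops",
    "GLIDER_COLUMNS",
]

# canonical glider CSV / NetCDF schema
GLIDER_COLUMNS = [
    "time",
    "lat",
    "lon",
    "depth_m",
    "temp_C",
    "sal_psu",
    "chl_fl_mg_m3",
    "cdom_fl",
    "bbp700_m1",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class GliderProfile:
    """One dive or climb: a contiguous, time-ordered slice of records."""

    records: pd.DataFrame
    direction: str  # "dive" | "climb"

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# despiking
# ---------------------------------------------------------------------------

def despike(series, window: int = 7, n_mad: float = 5.0, scale_window: int | None = None):
    """Mask spikes by a rolling median / MAD criterion.

    A sample is a spike when it deviates from the centred rolling median
    of its *neighbours* (centre sample excluded, so the reference cannot
    absorb the spike) by more than ``n_mad`` robust standard deviations,
    estimated as 1.4826 x the rolling median absolute deviation over
    ``scale_window`` samples (default ``5 * window``, for a stable scale
    estimate).  Samples whose neighbour window is one-sided (the first
    and last half-window of the series) are never flagged.

    Returns ``(cleaned, mask)`` where ``cleaned`` has spikes replaced by
    NaN and all other samples unchanged, and ``mask`` is True at spikes.
    Intended for use on individual monotone profiles; on a full sawtooth
    series the vertical gradient at turning points can masquerade as a
    spike.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    values = np.asarray(series, dtype=float)
    if values.size < window:
        warnings.warn("series shorter than despike window; returned unchanged")
        return values.copy(), np.zeros(values.shape, dtype=bool)
    if scale_window is None:
        scale_window = 5 * window
    k = window // 2
    sk = scale_window // 2

    def flag(vals: np.ndarray) -> np.ndarray:
        pad = np.concatenate([np.full(k, np.nan), vals, np.full(k, np.nan)])
        win = np.lib.stride_tricks.sliding_window_view(pad, window).copy()
        win[:, k] = np.nan  # exclude the centre sample from its own reference
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(win, axis=1)
            dev = np.abs(vals - med)
            pad_dev = np.concatenate([np.full(sk, np.nan), dev, np.full(sk, np.nan)])
            dwin = np.lib.stride_tricks.sliding_window_view(pad_dev, 2 * sk + 1)
            mad = np.nanmedian(dwin, axis=1)
        with np.errstate(invalid="ignore"):
            m = dev > n_mad * 1.4826 * mad
        m &= np.isfinite(vals)
        m[:k] = False  # one-sided windows at the ends are exempt
        m[-k:] = False
        return m

    # iterate to a fixed point so the operation is idempotent by
    # construction (a re-run on its own output flags nothing new)
    cleaned = values.copy()
    mask = np.zeros(values.shape, dtype=bool)
    for _ in range(10):
        new = flag(cleaned)
        if not new.any():
            break
        mask |= new
        cleaned[new] = np.nan
    return cleaned, mask


# ---------------------------------------------------------------------------
# profile separation
# ---------------------------------------------------------------------------

def split_profiles(records: pd.DataFrame, hysteresis: float = 5.0) -> list[GliderProfile]:
    """Separate a sawtooth depth record into dive and climb profiles.

    A turning point is declared when depth reverses by more than
    ``hysteresis`` metres from the running extremum; the profile is cut
    at the extremum so every record belongs to exactly one profile.
    """
    depth = records["depth_m"].to_numpy(dtype=float)
    n = len(depth)
    if n == 0:
        return []

    profiles: list[GliderProfile] = []
    start = 0
    direction: str | None = None
    vmax = vmin = depth[0]
    imax = imin = 0

    def close(end_idx: int, direc: str, new_start: int):
        nonlocal start, vmax, vmin, imax, imin
        profiles.append(
            GliderProfile(records.iloc[start : end_idx + 1].copy(), direc)
        )
        start = new_start
        seg = depth[new_start : i + 1]
        off = new_start
        imax_, imin_ = int(np.argmax(seg)), int(np.argmin(seg))
        vmax, imax = seg[imax_], off + imax_
        vmin, imin = seg[imin_], off + imin_

    for i in range(1, n):
        d = depth[i]
        if d > vmax:
            vmax, imax = d, i
        if d < vmin:
            vmin, imin = d, i
        if direction is None:
            if d > vmin + hysteresis:
                direction = "dive"
            elif d < vmax - hysteresis:
                direction = "climb"
        elif direction == "dive" and d < vmax - hysteresis:
            close(imax, "dive", imax + 1)
            direction = "climb"
        elif direction == "climb" and d > vmin + hysteresis:
            close(imin, "climb", imin + 1)
            direction = "dive"

    i = n - 1
    profiles.append(
        GliderProfile(records.iloc[start:].copy(), direction or "dive")
    )
    return profiles


def along_track_distance(lat, lon) -> np.ndarray:
    """Cumulative great-circle distance (km) along the glider track."""
    lat = np.radians(np.asarray(lat, dtype=float))
    lon = np.radians(np.asarray(lon, dtype=float))
    dlat = np.diff(lat)
    dlon = np.diff(lon)
    h = (
        np.sin(dlat / 2) ** 2
        + np.cos(lat[:-1]) * np.cos(lat[1:]) * np.sin(dlon / 2) ** 2
    )
    seg = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))
    return np.concatenate([[0.0], np.cumsum(seg)])


# ---------------------------------------------------------------------------
# hybrid chlorophyll
# ---------------------------------------------------------------------------

def chl_from_bbp(bbp700, coeffs: ModelCoefficients = DEFAULT):
    """Invert the 700 nm backscattering power law to chlorophyll.

    ``chl = (bbp700 / A_bb(700))**(1 / B_bb(700))``.
    """
    bbp700 = np.asarray(bbp700, dtype=float)
    if np.any(bbp700[np.isfinite(bbp700)] <= 0):
        raise ValueError("bbp700 must be > 0 to invert the power law")
    a, b = coeffs.bbp_table.interp(700.0)
    out = np.power(bbp700 / a, 1.0 / b)
    return float(out) if np.ndim(out) == 0 else out


def hybrid_chl(
    chl_fl,
    bbp700,
    threshold: float | None = None,
    coeffs: ModelCoefficients = DEFAULT,
):
    """Hybrid chlorophyll estimate with a source flag per sample.

    Fluorescence-derived Chl is used up to (and including) the switching
    threshold (default 2 mg m^-3); above it, Chl is recovered from the
    700 nm backscattering channel, which is immune to fluorescence
    quenching.  The switch is hard (no blending).  Returns
    ``(chl, flags)`` with flags "fluorescence" or "backscatter".
    """
    if threshold is None:
        threshold = coeffs.chl_switch
    chl_fl = np.asarray(chl_fl, dtype=float)
    bbp700 = np.asarray(bbp700, dtype=float)
    if np.any(chl_fl[np.isfinite(chl_fl)] < 0):
        raise ValueError("chl_fl must be >= 0")
    scalar = chl_fl.ndim == 0 and bbp700.ndim == 0
    chl_fl, bbp700 = np.atleast_1d(chl_fl), np.atleast_1d(bbp700)
    chl_fl, bbp700 = np.broadcast_arrays(chl_fl, bbp700)

    use_bb = chl_fl > threshold
    chl = chl_fl.astype(float).copy()
    if np.any(use_bb):
        chl[use_bb] = chl_from_bbp(bbp700[use_bb], coeffs)
    flags = np.where(use_bb, "backscatter", "fluorescence")
    if scalar:
        return float(chl[0]), str(flags[0])
    return chl, flags


# ---------------------------------------------------------------------------
# Barnes objective analysis
# ---------------------------------------------------------------------------

def _barnes_pass(
    xt: np.ndarray,
    zt: np.ndarray,
    xs: np.ndarray,
    zs: np.ndarray,
    values: np.ndarray,
    lx: float,
    lz: float,
    cutoff: float,
    chunk: int = 2048,
) -> np.ndarray:
    """Gaussian-weighted average of ``values`` at target points.

    Weights ``exp(-d2)`` with ``d2 = (dx/lx)^2 + (dz/lz)^2``, truncated
    at normalized distance ``cutoff``.  Sources must be sorted by x.
    Targets with no source inside the cutoff get NaN.
    """
    out = np.full(xt.shape, np.nan)
    xmax = cutoff * lx
    c2 = cutoff * cutoff
    for i0 in range(0, xt.size, chunk):
        sl = slice(i0, min(i0 + chunk, xt.size))
        xt_c, zt_c = xt[sl], zt[sl]
        lo = np.searchsorted(xs, xt_c.min() - xmax, side="left")
        hi = np.searchsorted(xs, xt_c.max() + xmax, side="right")
        if hi <= lo:
            continue
        dx = (xt_c[:, None] - xs[None, lo:hi]) / lx
        dz = (zt_c[:, None] - zs[None, lo:hi]) / lz
        d2 = dx * dx + dz * dz
        w = np.where(d2 <= c2, np.exp(-d2), 0.0)
        denom = w.sum(axis=1)
        ok = denom > 0
        num = w @ values[lo:hi]
        res = np.full(xt_c.shape, np.nan)
        res[ok] = num[ok] / denom[ok]
        out[sl] = res
    return out


def barnes_grid(
    x,
    z,
    values,
    x_grid,
    z_grid,
    radii: tuple[float, float] = (10.0, 10.0),
    passes: int = 2,
    gamma: float = 0.3,
    cutoff: float = 3.0,
) -> np.ndarray:
    """Barnes successive-correction analysis onto a regular grid.

    Observations ``(x km, z m, value)`` are mapped to the grid with
    Gaussian weights of length scales ``radii``; correction pass ``p``
    uses length scales scaled by ``gamma**(p-1)``.  Grid cells farther
    than ``cutoff`` (normalized, elliptical) first-pass radii from every
    observation are NaN.  Returns an array of shape
    ``(len(z_grid), len(x_grid))``.
    """
    if passes < 1:
        raise ValueError("passes must be >= 1")
    if not 0 < gamma <= 1:
        raise ValueError("gamma must be in (0, 1]")
    lx, lz = map(float, radii)
    if lx <= 0 or lz <= 0:
        raise ValueError("radii must be > 0")

    x = np.asarray(x, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    v = np.asarray(values, dtype=float).ravel()
    keep = np.isfinite(x) & np.isfinite(z) & np.isfinite(v)
    x, z, v = x[keep], z[keep], v[keep]
    x_grid = np.asarray(x_grid, dtype=float)
    z_grid = np.asarray(z_grid, dtype=float)
    nz, nx = z_grid.size, x_grid.size
    if x.size == 0:
        return np.full((nz, nx), np.nan)

    order = np.argsort(x, kind="stable")
    x, z, v = x[order], z[order], v[order]

    gx, gz = np.meshgrid(x_grid, z_grid)  # (nz, nx)
    gxf, gzf = gx.ravel(), gz.ravel()

    grid_est = _barnes_pass(gxf, gzf, x, z, v, lx, lz, cutoff)
    obs_est = _barnes_pass(x, z, x, z, v, lx, lz, cutoff)
    for p in range(2, passes + 1):
        scale = gamma ** (p - 1)
        resid = v - obs_est
        corr = _barnes_pass(gxf, gzf, x, z, resid, lx * scale, lz * scale, cutoff)
        grid_est = grid_est + np.where(np.isnan(corr) & ~np.isnan(grid_est), 0.0, corr)
        if p < passes:
            ocorr = _barnes_pass(x, z, x, z, resid, lx * scale, lz * scale, cutoff)
            obs_est = obs_est + np.where(np.isnan(ocorr), 0.0, ocorr)

    return grid_est.reshape(nz, nx)


def grid_transect(
    records: pd.DataFrame,
    fields: dict[str, np.ndarray] | None = None,
    spacing: tuple[float, float] = (2.0, 5.0),
    radii: tuple[float, float] = (10.0, 10.0),
    passes: int = 2,
    gamma: float = 0.3,
    cutoff: float = 3.0,
) -> xr.Dataset:
    """Grid glider records onto a regular along-track x depth raster.

    The along-track coordinate is cumulative great-circle distance (km);
    cell centres sit at multiples of the spacings (default 2 km x 5 m)
    starting at the first record.  ``fields`` maps output names to value
    arrays aligned with ``records``; by default temperature, salinity,
    chl (if present) and bbp700 are gridded.
    """
    dist = along_track_distance(records["lat"], records["lon"])
    depth = records["depth_m"].to_numpy(dtype=float)

    dx, dz = spacing
    x_grid = np.arange(0.0, dist.max() + dx / 2, dx)
    z_grid = np.arange(0.0, depth.max() + dz / 2, dz)

    if fields is None:
        fields = {
            "temperature": records["temp_C"].to_numpy(dtype=float),
            "salinity": records["sal_psu"].to_numpy(dtype=float),
            "bbp700": records["bbp700_m1"].to_numpy(dtype=float),
        }
        if "chl" in records:
            fields["chl"] = records["chl"].to_numpy(dtype=float)

    data = {}
    for name, vals in fields.items():
        grid = barnes_grid(
            dist, depth, vals, x_grid, z_grid,
            radii=radii, passes=passes, gamma=gamma, cutoff=cutoff,
        )
        data[name] = (("depth_m", "along_track_km"), grid)

    ds = xr.Dataset(
        data,
        coords={"depth_m": z_grid, "along_track_km": x_grid},
        attrs={
            "spacing_km_m": list(spacing),
            "radii_km_m": list(radii),
            "passes": passes,
            "gamma": gamma,
            "cutoff": cutoff,
        },
    )
    return ds


# ---------------------------------------------------------------------------
# gridded IOPs
# ---------------------------------------------------------------------------

def transect_iops(
    transect: xr.Dataset,
    wavelengths=None,
    coeffs: ModelCoefficients = DEFAULT,
    temperature_default: float = 10.0,
) -> xr.Dataset:
    """Apply the forward bio-optical model cell-wise to a gridded transect.

    Requires ``chl`` and ``salinity`` fields; missing cells propagate as
    NaN.  Adds wavelength-resolved totals (``a_total``, ``b_total``,
    ``bb_total``), non-water absorption ``a_nw`` and the particulate
    terms ``b_p`` and ``b_bp``.
    """
    if "chl" not in transect or "salinity" not in transect:
        raise ValueError("transect must contain 'chl' and 'salinity' fields")
    lam = np.atleast_1d(
        np.asarray(
            coeffs.model_wavelengths if wavelengths is None else wavelengths,
            dtype=float,
        )
    )
    chl = transect["chl"].values
    sal = transect["salinity"].values
    if "temperature" in transect:
        temp = transect["temperature"].values
    else:
        temp = np.full_like(chl, temperature_default)

    shape = (lam.size,) + chl.shape
    a_tot = np.empty(shape)
    b_tot = np.empty(shape)
    bb_tot = np.empty(shape)
    a_nw = np.empty(shape)
    b_p = np.empty(shape)
    b_bp = np.empty(shape)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for k, lk in enumerate(lam):
            a_w = pure_water_absorption(lk)
            b_w, bb_w = pure_seawater_scattering(lk, np.nan_to_num(sal, nan=35.0), temp)
            a_ph = model.aph(lk, chl, coeffs)
            a_nap = model.anap(lk, chl, coeffs)
            a_cd = model.acdom(lk, sal, coeffs)
            bp_k = model.bp(lk, chl, coeffs)
            bbp_k = model.bbp(lk, chl, coeffs)
            nanmask = ~np.isfinite(sal)
            a_nw[k] = a_cd + a_ph + a_nap
            a_tot[k] = a_w + a_nw[k]
            b_p[k] = bp_k
            b_bp[k] = bbp_k
            b_tot[k] = np.where(nanmask, np.nan, b_w) + bp_k
            bb_tot[k] = np.where(nanmask, np.nan, bb_w) + bbp_k

    out = transect.copy()
    dims = ("wavelength_nm",) + tuple(transect["chl"].dims)
    out = out.assign_coords(wavelength_nm=lam)
    for name, arr in [
        ("a_total", a_tot),
        ("b_total", b_tot),
        ("bb_total", bb_tot),
        ("a_nw", a_nw),
        ("b_p", b_p),
        ("b_bp", b_bp),
    ]:
        out[name] = (dims, arr)
        out[name].attrs["units"] = "m-1"
    return out
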