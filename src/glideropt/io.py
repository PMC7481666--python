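"""File I/O, pipeline configuration and the end-to-end pipeline driver."""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import glider as gl
from . import model
from .coefficients import DEFAULT, ModelCoefficients
from .reflectance import RrsSpectrum, compare_ensembles, glider_rrs
from .water import pure_seawater_scattering

log = logging.getLogger("glideropt")

__all__ = [
    "PipelineConfig",
    "read_glider",
    "write_glider",
    "read_satellite_rrs",
    "write_rrs_csv",
    "read_rrs_csv",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """All tunable constants of the glider -> IOP -> Rrs pipeline.

    Defaults reproduce the model's stated constants; everything is
    overridable from YAML or CLI flags.
    """

    wavelengths: list[float] = field(
        default_factory=lambda: [440.0, 488.0, 510.0, 532.0, 555.0, 650.0, 676.0, 700.0, 715.0]
    )
    spacing: tuple[float, float] = (2.0, 5.0)  # km, m
    radii: tuple[float, float] = (10.0, 10.0)  # km, m (first Barnes pass)
    passes: int = 2
    gamma: float = 0.3
    cutoff: float = 3.0
    despike_window: int = 7
    despike_nmad: float = 5.0
    hysteresis_m: float = 5.0
    hybrid_threshold: float = 2.0
    band_tolerance_nm: float = 10.0
    surface_depth_m: float = 2.0
    temperature_default: float = 10.0
    subtract_water_bb: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spacing"] = list(self.spacing)
        d["radii"] = list(self.radii)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("spacing", "radii"):
            if key in d:
                d[key] = tuple(float(v) for v in d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


# ---------------------------------------------------------------------------
# glider records
# ---------------------------------------------------------------------------

def read_glider(path, fmt: str | None = None) -> pd.DataFrame:
    """Read glider records from CSV or NetCDF into the canonical schema.

    Validates the column set and strict time monotonicity, and logs
    basic unit sanity checks.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "netcdf" if path.suffix in {".nc", ".cdf"} else "csv"
    if fmt == "csv":
        df = pd.read_csv(path)
    elif fmt == "netcdf":
        ds = xr.open_dataset(path, engine="scipy")
        df = ds.to_dataframe().reset_index()
        ds.close()
    else:
        raise ValueError(f"unknown glider format {fmt!r}")

    missing = [c for c in gl.GLIDER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"glider file missing required columns: {missing}")
    df = df[gl.GLIDER_COLUMNS].copy()
    df["time"] = pd.to_datetime(df["time"])
    t = df["time"].to_numpy()
    if np.any(np.diff(t.astype("datetime64[ns]").astype(np.int64)) <= 0):
        raise ValueError("glider time axis is not strictly increasing")

    sal = df["sal_psu"].to_numpy(dtype=float)
    if np.any((sal < 0) | (sal > 40)):
        log.warning("salinity values outside [0, 40] PSU present")
    if np.any(df["depth_m"].to_numpy(dtype=float) < 0):
        log.warning("negative depths present")
    log.info("read %d glider records from %s", len(df), path)
    return df


def write_glider(df: pd.DataFrame, path) -> None:
    """Write glider records to CSV (or NetCDF for .nc paths)."""
    path = Path(path)
    out = df.copy()
    if path.suffix in {".nc", ".cdf"}:
        ds = out.set_index("time").to_xarray()
        ds.to_netcdf(path, engine="scipy")
    else:
        out["time"] = pd.to_datetime(out["time"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
        out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Rrs tables
# ---------------------------------------------------------------------------

def read_satellite_rrs(path) -> list[RrsSpectrum]:
    """Read satellite Rrs spectra from a long-format CSV.

    Required columns: ``band_nm`` and ``rrs_sr_1``; an optional
    ``spectrum_id`` column separates multiple spectra (one spectrum
    assumed otherwise).
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("band_nm", "rrs_sr_1") if c not in df.columns]
    if missing:
        raise ValueError(f"satellite Rrs file missing columns: {missing}")
    if "spectrum_id" not in df.columns:
        df["spectrum_id"] = 0
    spectra = []
    for _, grp in df.groupby("spectrum_id", sort=True):
        grp = grp.sort_values("band_nm")
        spectra.append(
            RrsSpectrum(
                grp["band_nm"].to_numpy(dtype=float),
                grp["rrs_sr_1"].to_numpy(dtype=float),
                provenance="satellite",
            )
        )
    return spectra


def write_rrs_csv(spectra: list[RrsSpectrum], path) -> None:
    rows = []
    for i, sp in enumerate(spectra):
        for lam, r in zip(sp.wavelengths, sp.rrs):
            rows.append(
                {"spectrum_id": i, "band_nm": lam, "rrs_sr_1": r, "provenance": sp.provenance}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rrs_csv(path) -> list[RrsSpectrum]:
    df = pd.read_csv(path, comment="#")
    spectra = []
    for _, grp in df.groupby("spectrum_id", sort=True):
        grp = grp.sort_values("band_nm")
        spectra.append(
            RrsSpectrum(
                grp["band_nm"].to_numpy(dtype=float),
                grp["rrs_sr_1"].to_numpy(dtype=float),
                provenance=str(grp["provenance"].iloc[0]) if "provenance" in grp else "glider",
            )
        )
    return spectra


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def process_records(
    records: pd.DataFrame,
    config: PipelineConfig,
    coeffs: ModelCoefficients = DEFAULT,
) -> pd.DataFrame:
    """Split, despike per profile and attach the hybrid Chl estimate.

    Despiking runs within individual dive/climb profiles (monotone
    depth) so vertical structure at turning points is not mistaken for
    spikes.
    """
    df = records.copy()
    profiles = gl.split_profiles(df, hysteresis=config.hysteresis_m)
    n_spikes = {}
    for col in ("chl_fl_mg_m3", "bbp700_m1"):
        cleaned = df[col].to_numpy(dtype=float).copy()
        count = 0
        pos = 0
        for prof in profiles:
            m = len(prof)
            seg, mask = gl.despike(
                cleaned[pos : pos + m],
                window=config.despike_window,
                n_mad=config.despike_nmad,
            )
            cleaned[pos : pos + m] = seg
            count += int(mask.sum())
            pos += m
        df[col] = cleaned
        n_spikes[col] = count
    log.info("masked spikes: %s", n_spikes)

    bbp = df["bbp700_m1"].to_numpy(dtype=float)
    if config.subtract_water_bb:
        _, bb_w = pure_seawater_scattering(
            700.0, df["sal_psu"].to_numpy(dtype=float), df["temp_C"].to_numpy(dtype=float)
        )
        bbp = np.clip(bbp - bb_w, 1e-8, None)
    chl, flags = gl.hybrid_chl(
        df["chl_fl_mg_m3"].to_numpy(dtype=float),
        bbp,
        threshold=config.hybrid_threshold,
        coeffs=coeffs,
    )
    df["chl"] = chl
    df["chl_source"] = flags
    return df


def run_pipeline(
    config: PipelineConfig,
    glider_path,
    satellite_path=None,
    outdir=".",
    coeffs: ModelCoefficients = DEFAULT,
) -> dict:
    """Run glider records through despiking, gridding, IOPs and Rrs.

    Writes the gridded transect (NetCDF), the per-column glider Rrs
    spectra (CSV) and, when a satellite table is given, the band-matched
    comparison summary (CSV + JSON).  Deterministic for fixed inputs and
    config.  Returns the in-memory products.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records = read_glider(glider_path)
    df = process_records(records, config, coeffs)

    profiles = gl.split_profiles(df, hysteresis=config.hysteresis_m)
    log.info("separated %d profiles", len(profiles))

    transect = gl.grid_transect(
        df,
        fields={
            "temperature": df["temp_C"].to_numpy(dtype=float),
            "salinity": df["sal_psu"].to_numpy(dtype=float),
            "chl": df["chl"].to_numpy(dtype=float),
            "bbp700": df["bbp700_m1"].to_numpy(dtype=float),
        },
        spacing=config.spacing,
        radii=config.radii,
        passes=config.passes,
        gamma=config.gamma,
        cutoff=config.cutoff,
    )
    n_cells = int(np.isfinite(transect["chl"].values).sum())
    log.info("gridded transect: %d valid cells", n_cells)

    transect = gl.transect_iops(
        transect,
        wavelengths=config.wavelengths,
        coeffs=coeffs,
        temperature_default=config.temperature_default,
    )
    spectra = glider_rrs(
        transect, depth_limit=config.surface_depth_m, coeffs=coeffs
    )
    log.info("computed %d glider Rrs spectra", len(spectra))

    transect_path = outdir / "transect.nc"
    transect.to_netcdf(transect_path, engine="scipy")
    rrs_path = outdir / "rrs_glider.csv"
    write_rrs_csv(spectra, rrs_path)
    config.to_yaml(outdir / "effective_config.yaml")

    out = {
        "transect": transect,
        "rrs": spectra,
        "profiles": profiles,
        "records": df,
        "paths": {"transect": transect_path, "rrs": rrs_path},
    }

    if satellite_path is not None:
        satellite = read_satellite_rrs(satellite_path)
        summary = compare_ensembles(
            spectra, satellite, tolerance=config.band_tolerance_nm
        )
        log.info(
            "matched %d bands, mean error %.1f%%",
            len(summary.bands),
            summary.mean_error,
        )
        summary.bands.to_csv(outdir / "comparison.csv", index=False)
        (outdir / "comparison.json").write_text(
            json.dumps(summary.to_json_dict(), indent=2)
        )
        out["comparison"] = summary
        out["paths"]["comparison"] = outdir / "comparison.json"

    return out
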