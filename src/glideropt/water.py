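"""Pure (sea)water inherent optical properties.

The fixed water baseline of the bulk-IOP sums: absorption from an
embedded literature table (linear interpolation in wavelength) and a
power-law molecular scattering parameterization with explicit salinity
and temperature dependence.  Backscattering is half the scattering
coefficient (symmetric molecular phase function).
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "WaterIOPs",
    "pure_water_absorption",
    "pure_seawater_scattering",
    "water_iops",
    "WAVELENGTH_RANGE",
]

WAVELENGTH_RANGE = (380.0, 750.0)


@dataclass(frozen=True)
class WaterIOPs:
    """Water absorption, scattering and backscattering at one wavelength."""

    wavelength: float
    a_w: float
    b_w: float
    bb_w: float


@lru_cache(maxsize=1)
def _absorption_table() -> tuple[np.ndarray, np.ndarray]:
    with resources.files("glideropt.data").joinpath(
        "pure_water_absorption.csv"
    ).open() as fh:
        df = pd.read_csv(fh, comment="#").sort_values("wavelength_nm")
    return (
        df["wavelength_nm"].to_numpy(dtype=float),
        df["a_w_m1"].to_numpy(dtype=float),
    )


@lru_cache(maxsize=1)
def _scattering_params() -> dict[str, float]:
    with resources.files("glideropt.data").joinpath(
        "seawater_scattering.csv"
    ).open() as fh:
        df = pd.read_csv(fh, comment="#")
    return dict(zip(df["parameter"], df["value"].astype(float)))


def _check_wavelength(wavelength) -> np.ndarray:
    lam = np.asarray(wavelength, dtype=float)
    lo, hi = WAVELENGTH_RANGE
    if np.any(lam < lo) or np.any(lam > hi):
        raise ValueError(
            f"wavelength outside valid range [{lo:g}, {hi:g}] nm"
        )
    return lam


def pure_water_absorption(wavelength):
    """Pure-water absorption coefficient a_w (m^-1).

    Linear interpolation of the embedded literature table; exact at the
    tabulated wavelengths.  Valid for 380-750 nm.
    """
    lam = _check_wavelength(wavelength)
    knots, values = _absorption_table()
    out = np.interp(lam, knots, values)
    return out if out.ndim else float(out)

def pure_seawater_scattering(wavelength, salinity=35.0, temperature=10.0):
    """Pure-seawater scattering and backscattering coefficients (m^-1).

    Power-law in wavelength (~lambda^-4.3) with a linear salinity
    enhancement and a weak linear temperature term; see the provenance
    header of ``data/seawater_scattering.csv``.  Returns ``(b_w, bb_w)``
    with ``bb_w = b_w / 2``.
    """
    lam = _check_wavelength(wavelength)
    sal = np.asarray(salinity, dtype=float)
    if np.any(sal < 0) or np.any(sal > 40):
        raise ValueError("salinity outside valid range [0, 40] PSU")
    p = _scattering_params()
    b_w = (
        p["b_ref_m1"]
        * (p["lambda_ref_nm"] / lam) ** p["exponent"]
        * (1.0 + p["salinity_gain"] * sal / p["salinity_ref_psu"])
        * (1.0 + p["temp_gain_per_degC"] * (np.asarray(temperature, float) - p["temp_ref_degC"]))
    )
    bb_w = 0.5 * b_w
    if np.ndim(b_w) == 0:
        return float(b_w), float(bb_w)
    return b_w, bb_w


def water_iops(wavelength: float, salinity: float = 35.0, temperature: float = 10.0) -> WaterIOPs:
    """Bundle a_w, b_w and bb_w at a single wavelength."""
    a_w = pure_water_absorption(wavelength)
    b_w, bb_w = pure_seawater_scattering(wavelength, salinity, temperature)
    return WaterIOPs(wavelength=float(wavelength), a_w=a_w, b_w=b_w, bb_w=bb_w)
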