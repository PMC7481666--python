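"""Pinned model coefficients and their loaders.

All empirical constants of the bio-optical model live here: the
power-law tables for phytoplankton absorption, particulate scattering
and backscattering, the NAP and CDOM absorption constants, and the
reflectance-model constants.  Tables are shipped as plain-text CSV data
files with provenance headers and loaded once at import.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["CoefficientTable", "ModelCoefficients", "load_coefficients"]


def _read_data_csv(name: str) -> pd.DataFrame:
    with resources.files("glideropt.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


@dataclass(frozen=True)
class CoefficientTable:
    """Per-wavelength (amplitude, exponent) pairs of one power law.

    Evaluates ``A(lambda) * chl ** E(lambda)`` with A and E interpolated
    linearly and independently between tabulated wavelengths.  No
    extrapolation outside the tabulated span.
    """

    wavelengths: np.ndarray
    amplitude: np.ndarray
    exponent: np.ndarray
    amplitude_ci_factor: np.ndarray | None = None
    exponent_ci: np.ndarray | None = None

    @property
    def wavelength_range(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def check_wavelength(self, wavelength, label: str = "wavelength") -> np.ndarray:
        lam = np.asarray(wavelength, dtype=float)
        lo, hi = self.wavelength_range
        if np.any(lam < lo) or np.any(lam > hi):
            raise ValueError(
                f"{label} outside tabulated range [{lo:g}, {hi:g}] nm"
            )
        return lam

    def interp(self, wavelength) -> tuple[np.ndarray, np.ndarray]:
        """Linearly interpolated (amplitude, exponent) at ``wavelength``."""
        lam = self.check_wavelength(wavelength)
        a = np.interp(lam, self.wavelengths, self.amplitude)
        e = np.interp(lam, self.wavelengths, self.exponent)
        return a, e

    def evaluate(self, wavelength, chl) -> np.ndarray:
        chl = np.asarray(chl, dtype=float)
        if np.any(chl < 0):
            raise ValueError("chlorophyll concentration must be >= 0")
        a, e = self.interp(wavelength)
        return a * np.power(chl, e)

    @classmethod
    def from_csv(
        cls,
        name: str,
        amplitude_col: str,
        exponent_col: str,
        exponent_offset: float = 0.0,
    ) -> "CoefficientTable":
        df = _read_data_csv(name).sort_values("wavelength_nm")
        return cls(
            wavelengths=df["wavelength_nm"].to_numpy(dtype=float),
            amplitude=df[amplitude_col].to_numpy(dtype=float),
            exponent=df[exponent_col].to_numpy(dtype=float) + exponent_offset,
            amplitude_ci_factor=(
                df["A_ci_factor"].to_numpy(dtype=float)
                if "A_ci_factor" in df
                else None
            ),
            exponent_ci=(
                df["B_ci"].to_numpy(dtype=float) if "B_ci" in df else None
            ),
        )


@dataclass(frozen=True)
class ModelCoefficients:
    """Every printed constant of the bio-optical model in one place."""

    aph_table: CoefficientTable
    bp_table: CoefficientTable
    bbp_table: CoefficientTable
    # non-algal particle absorption: anap(440) = nap_ref_coeff * Chl^nap_exp,
    # spectral shape exp(-nap_slope * (lambda - 440))
    nap_ref_coeff: float = 0.0124
    nap_exp: float = 0.724
    nap_slope: float = 0.011
    # CDOM: acdom(440) = cdom_sal_slope * Sal + cdom_sal_intercept,
    # spectral shape exp(-cdom_spectral_slope * (lambda - 440))
    cdom_sal_slope: float = -0.012
    cdom_sal_intercept: float = 0.464
    cdom_spectral_slope: float = 0.0168
    sal_valid: tuple[float, float] = (27.0, 35.0)
    cdom_fallback: float = 0.04
    # reflectance model constants
    fq_ratio: float = 0.0922
    fresnel_r: float = 0.021
    n_water: float = 1.34
    # hybrid chlorophyll estimator switch
    chl_switch: float = 2.0
    reference_wavelength: float = 440.0

    @property
    def model_wavelengths(self) -> np.ndarray:
        """The nine wavelengths at which full IOP bundles are defined.

        412 nm is excluded because the backscattering table has no entry
        there; 700 nm (the triplet backscattering channel) is included.
        """
        return self.bbp_table.wavelengths.copy()


def load_coefficients() -> ModelCoefficients:
    """Load the shipped coefficient tables into a :class:`ModelCoefficients`."""
    # aph stored as (A_ph, B_ph) with a_ph = A_ph * Chl^(1 + B_ph)
    aph = CoefficientTable.from_csv(
        "aph_coefficients.csv", "A_ph", "B_ph", exponent_offset=1.0
    )
    bp = CoefficientTable.from_csv("bp_coefficients.csv", "A_b", "B_b")
    bbp = CoefficientTable.from_csv("bbp_coefficients.csv", "A_bb", "B_bb")
    return ModelCoefficients(aph_table=aph, bp_table=bp, bbp_table=bbp)


DEFAULT = load_coefficients()
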