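"""Core forward bio-optical model.

Computes each partial inherent optical property (IOP) from chlorophyll
concentration and salinity, and assembles bulk spectral absorption,
scattering and backscattering as the sum of water plus constituent
terms:

    a(lambda)  = a_w + a_CDOM(Sal) + a_ph(Chl) + a_nap(Chl)
    b(lambda)  = b_w + b_p(Chl)
    bb(lambda) = bb_w + b_bp(Chl)

Phytoplankton, particulate scattering and particulate backscattering
follow per-wavelength power laws in Chl with tabulated coefficients;
non-algal particles and CDOM follow exponential spectral shapes anchored
at 440 nm.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .coefficients import DEFAULT, ModelCoefficients
from .water import pure_seawater_scattering, pure_water_absorption

__all__ = [
    "Spectrum",
    "IOPBundle",
    "aph",
    "anap",
    "acdom",
    "bp",
    "bbp",
    "total_iops",
]

_IOP_KINDS = {"absorption", "scattering", "backscattering", "reflectance"}


@dataclass
class Spectrum:
    """A wavelength-indexed optical coefficient vector."""

    wavelengths: np.ndarray
    values: np.ndarray
    quantity_kind: str = "absorption"

    def __post_init__(self):
        self.wavelengths = np.atleast_1d(np.asarray(self.wavelengths, dtype=float))
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if self.quantity_kind not in _IOP_KINDS:
            raise ValueError(f"unknown quantity kind {self.quantity_kind!r}")
        if self.wavelengths.shape != self.values.shape:
            raise ValueError("wavelengths and values must have equal length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly ascending")
        if self.quantity_kind != "reflectance" and np.any(self.values < 0):
            raise ValueError("negative values in an IOP spectrum")

    def __len__(self) -> int:
        return len(self.wavelengths)

    def value_at(self, wavelength: float) -> float:
        idx = np.nonzero(np.isclose(self.wavelengths, wavelength))[0]
        if idx.size == 0:
            raise KeyError(f"{wavelength} nm not on this spectrum's grid")
        return float(self.values[idx[0]])


@dataclass
class IOPBundle:
    """Bulk spectral IOPs plus their named partial components."""

    a_total: Spectrum
    b_total: Spectrum
    bb_total: Spectrum
    a_components: dict[str, Spectrum] = field(default_factory=dict)
    b_components: dict[str, Spectrum] = field(default_factory=dict)
    bb_components: dict[str, Spectrum] = field(default_factory=dict)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.a_total.wavelengths

    @property
    def a_nw(self) -> Spectrum:
        """Non-water absorption: total minus the pure-water term."""
        return Spectrum(
            self.wavelengths,
            self.a_total.values - self.a_components["water"].values,
            "absorption",
        )


def _check_chl(chl) -> np.ndarray:
    chl = np.asarray(chl, dtype=float)
    if np.any(chl[np.isfinite(chl)] < 0):
        raise ValueError("chlorophyll concentration must be >= 0")
    return chl


def aph(wavelength, chl, coeffs: ModelCoefficients = DEFAULT):
    """Phytoplankton absorption: A_ph(lambda) * Chl^(1 + B_ph(lambda))."""
    chl = _check_chl(chl)
    out = coeffs.aph_table.evaluate(wavelength, chl)
    return float(out) if np.ndim(out) == 0 else out


def anap(wavelength, chl, coeffs: ModelCoefficients = DEFAULT):
    """Non-algal particle absorption.

    Power law in Chl at 440 nm with an exponential spectral slope:
    ``0.0124 * Chl^0.724 * exp(-0.011 (lambda - 440))``.
    """
    chl = _check_chl(chl)
    lam = np.asarray(wavelength, dtype=float)
    a440 = coeffs.nap_ref_coeff * np.power(chl, coeffs.nap_exp)
    out = a440 * np.exp(-coeffs.nap_slope * (lam - coeffs.reference_wavelength))
    return float(out) if np.ndim(out) == 0 else out


def acdom(
    wavelength,
    salinity,
    coeffs: ModelCoefficients = DEFAULT,
    raw: bool = False,
):
    """CDOM absorption from salinity.

    The 440 nm anchor is linear in salinity and valid for salinities in
    ``coeffs.sal_valid`` (27-35 PSU); outside that range the anchor is
    replaced by the constant fallback (0.04 m^-1) and a warning is
    emitted.  With ``raw=True`` the linear equation is always used (for
    model introspection and testing), clamping negative results to zero.
    The spectral shape is ``exp(-0.0168 (lambda - 440))``.
    """
    sal = np.asarray(salinity, dtype=float)
    if np.any(sal[np.isfinite(sal)] < 0):
        raise ValueError("salinity must be >= 0")
    lam = np.asarray(wavelength, dtype=float)
    a440 = coeffs.cdom_sal_slope * sal + coeffs.cdom_sal_intercept
    if raw:
        if np.any(a440[np.isfinite(a440)] < 0):
            warnings.warn(
                "CDOM-salinity relation produced negative absorption; clamped to 0",
                stacklevel=2,
            )
            a440 = np.clip(a440, 0.0, None)
    else:
        lo, hi = coeffs.sal_valid
        invalid = np.isfinite(sal) & ((sal < lo) | (sal > hi))
        if np.any(invalid):
            warnings.warn(
                f"salinity outside [{lo:g}, {hi:g}] PSU; using constant "
                f"aCDOM(440) fallback {coeffs.cdom_fallback:g} m^-1",
                stacklevel=2,
            )
            a440 = np.where(invalid, coeffs.cdom_fallback, a440)
    out = a440 * np.exp(
        -coeffs.cdom_spectral_slope * (lam - coeffs.reference_wavelength)
    )
    return float(out) if np.ndim(out) == 0 else out


def bp(wavelength, chl, coeffs: ModelCoefficients = DEFAULT):
    """Particulate scattering: A_b(lambda) * Chl^B_b(lambda), 412-715 nm."""
    chl = _check_chl(chl)
    out = coeffs.bp_table.evaluate(wavelength, chl)
    return float(out) if np.ndim(out) == 0 else out


def bbp(wavelength, chl, coeffs: ModelCoefficients = DEFAULT):
    """Particulate backscattering: A_bb(lambda) * Chl^B_bb(lambda), 440-715 nm.

    412 nm is rejected explicitly: that channel is excluded from the
    backscattering model for data-quality reasons.
    """
    lam = np.asarray(wavelength, dtype=float)
    if np.any(np.isclose(lam, 412.0)):
        raise ValueError(
            "backscattering at 412 nm is excluded from the model "
            "(channel removed for data-quality reasons)"
        )
    chl = _check_chl(chl)
    out = coeffs.bbp_table.evaluate(wavelength, chl)
    return float(out) if np.ndim(out) == 0 else out


def total_iops(
    wavelengths,
    chl: float,
    salinity: float,
    temperature: float = 10.0,
    coeffs: ModelCoefficients = DEFAULT,
    raw_cdom: bool = False,
) -> IOPBundle:
    """Assemble bulk spectral IOPs as sums of partial components.

    ``wavelengths`` must lie within every component table's coverage
    (440-715 nm for the full bundle).  Returns an :class:`IOPBundle`
    whose totals equal the sums of the listed components.
    """
    lam = np.atleast_1d(np.asarray(wavelengths, dtype=float))

    a_w = np.atleast_1d(pure_water_absorption(lam))
    b_w, bb_w = pure_seawater_scattering(lam, salinity, temperature)
    b_w = np.atleast_1d(b_w)
    bb_w = np.atleast_1d(bb_w)

    a_ph = np.atleast_1d(aph(lam, chl, coeffs))
    a_nap = np.atleast_1d(anap(lam, chl, coeffs))
    a_cdom = np.atleast_1d(acdom(lam, salinity, coeffs, raw=raw_cdom))
    b_p = np.atleast_1d(bp(lam, chl, coeffs))
    b_bp = np.atleast_1d(bbp(lam, chl, coeffs))

    def spec(values, kind):
        return Spectrum(lam, values, kind)

    return IOPBundle(
        a_total=spec(a_w + a_cdom + a_ph + a_nap, "absorption"),
        b_total=spec(b_w + b_p, "scattering"),
        bb_total=spec(bb_w + b_bp, "backscattering"),
        a_components={
            "water": spec(a_w, "absorption"),
            "cdom": spec(a_cdom, "absorption"),
            "phytoplankton": spec(a_ph, "absorption"),
            "nap": spec(a_nap, "absorption"),
        },
        b_components={
            "water": spec(b_w, "scattering"),
            "particulate": spec(b_p, "scattering"),
        },
        bb_components={
            "water": spec(bb_w, "backscattering"),
            "particulate": spec(b_bp, "backscattering"),
        },
    )
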