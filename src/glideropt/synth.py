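"""Synthetic glider deployments, truth fields and satellite ensembles.

Emulates a south-to-north transect crossing a polar front: a logistic
drop in temperature and salinity at the front latitude with elevated,
surface-intensified chlorophyll (and hence particulate backscattering)
on the northern side, plus sensor noise, daytime fluorescence quenching
and data spikes.  Every generator is a pure function of its parameters
and the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xarray as xr
from scipy.special import expit

from . import model
from .coefficients import DEFAULT, ModelCoefficients
from .glider import GLIDER_COLUMNS
from .reflectance import RrsSpectrum, glider_rrs

__all__ = [
    "FrontScenario",
    "TruthFields",
    "synth_truth_fields",
    "synth_glider_deployment",
    "synth_satellite_ensemble",
]


@dataclass(frozen=True)
class FrontScenario:
    """Parameters of the synthetic polar-front transect."""

    front_lat: float = 75.8
    front_width_deg: float = 0.12  # logistic e-folding width of the front
    south_ts: tuple[float, float] = (6.0, 35.0)  # Atlantic-side (T, S)
    north_ts: tuple[float, float] = (1.0, 34.2)  # Arctic-side (T, S)
    chl_background: float = 0.3
    chl_bloom_peak: float = 8.0
    bloom_depth_scale: float = 50.0
    noise: dict[str, float] = field(
        default_factory=lambda: {
            "temp_C": 0.002,
            "sal_psu": 0.0005,
            "chl_fl_mg_m3": 0.02,
            "bbp700_m1": 0.02,
            "cdom_fl": 0.02,
        }
    )
    spike_rate: float = 0.0
    quenching: float = 0.0  # fractional daytime suppression of chl_fl
    quench_depth: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if not self.north_ts[0] < self.south_ts[0]:
            raise ValueError("north temperature must be below south temperature")
        if not self.north_ts[1] < self.south_ts[1]:
            raise ValueError("north salinity must be below south salinity")
        if not self.chl_bloom_peak > self.chl_background:
            raise ValueError("chl_bloom_peak must exceed chl_background")
        for name, rate in [("spike_rate", self.spike_rate), ("quenching", self.quenching)]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TruthFields:
    """Smooth, deterministic truth fields for one scenario."""

    scenario: FrontScenario

    def _front_factor(self, lat):
        s = self.scenario
        return expit((np.asarray(lat, float) - s.front_lat) / s.front_width_deg)

    def temperature(self, lat, depth=0.0):
        s = self.scenario
        f = self._front_factor(lat)
        return s.south_ts[0] + (s.north_ts[0] - s.south_ts[0]) * f

    def salinity(self, lat, depth=0.0):
        s = self.scenario
        f = self._front_factor(lat)
        return s.south_ts[1] + (s.north_ts[1] - s.south_ts[1]) * f

    def chl(self, lat, depth=0.0):
        s = self.scenario
        f = self._front_factor(lat)
        z = np.asarray(depth, dtype=float)
        bloom = (s.chl_bloom_peak - s.chl_background) * f * np.exp(-z / s.bloom_depth_scale)
        return s.chl_background + bloom


def synth_truth_fields(scenario: FrontScenario) -> TruthFields:
    """Continuous truth functions for temperature, salinity and Chl."""
    return TruthFields(scenario)


def synth_glider_deployment(
    scenario: FrontScenario,
    start_lat: float = 74.8,
    end_lat: float = 76.8,
    lon: float = 30.0,
    dive_depth: float = 150.0,
    samples_per_profile: int = 60,
    n_profiles: int = 40,
    sample_interval_s: float = 60.0,
    start_time: str = "2018-04-27T00:00:00",
    coeffs: ModelCoefficients = DEFAULT,
):
    """Sample the truth fields along a sawtooth glider track.

    Returns ``(records, truth, spike_masks)``: the glider records in the
    canonical column schema, a truth sidecar frame (true Chl/T/S, day
    flag, quenching factor applied), and per-channel boolean spike
    masks.  ``chl_fl`` is the truth Chl suppressed by the scenario's
    quenching factor in the upper ``quench_depth`` during daytime hours
    (06-18 local); ``bbp700`` is the forward backscattering model
    applied to truth Chl.  Noise is multiplicative lognormal; spikes are
    additive at 10-100x the channel's median absolute deviation.
    """
    rng = np.random.default_rng(scenario.seed)
    truth = synth_truth_fields(scenario)

    n = n_profiles * samples_per_profile
    lat = np.linspace(start_lat, end_lat, n)
    lonv = np.full(n, float(lon))

    # sawtooth: alternate dives (0 -> dive_depth) and climbs
    leg = np.linspace(0.0, dive_depth, samples_per_profile)
    depth = np.concatenate(
        [leg if i % 2 == 0 else leg[::-1] for i in range(n_profiles)]
    )

    time = pd.date_range(
        start=start_time, periods=n, freq=pd.Timedelta(seconds=sample_interval_s)
    )
    hour = time.hour + time.minute / 60.0
    is_day = (hour >= 6.0) & (hour < 18.0)

    t_true = truth.temperature(lat, depth)
    s_true = truth.salinity(lat, depth)
    chl_true = truth.chl(lat, depth)

    quench_factor = np.ones(n)
    quench_factor[is_day & (depth < scenario.quench_depth)] = 1.0 - scenario.quenching

    def noisy(values, channel):
        sigma = scenario.noise.get(channel, 0.0)
        if sigma <= 0:
            return np.asarray(values, dtype=float).copy()
        return values * np.exp(sigma * rng.standard_normal(n))

    chl_fl = noisy(chl_true * quench_factor, "chl_fl_mg_m3")
    bbp700 = noisy(model.bbp(700.0, chl_true, coeffs), "bbp700_m1")
    temp = noisy(t_true, "temp_C")
    sal = noisy(s_true, "sal_psu")
    # CDOM fluorescence in relative units, tracking the salinity-driven
    # CDOM absorption anchor
    cdom_fl = noisy(100.0 * model.acdom(440.0, s_true, coeffs), "cdom_fl")

    spike_masks = {}
    for name, arr in [("chl_fl_mg_m3", chl_fl), ("bbp700_m1", bbp700)]:
        mask = rng.random(n) < scenario.spike_rate
        if mask.any():
            med = np.median(arr)
            mad = np.median(np.abs(arr - med))
            scale = max(mad, 1e-6 * max(abs(med), 1.0))
            amp = rng.uniform(10.0, 100.0, mask.sum()) * scale
            arr[mask] += amp  # positive spikes, as from bubbles/aggregates
        spike_masks[name] = mask

    records = pd.DataFrame(
        {
            "time": time,
            "lat": lat,
            "lon": lonv,
            "depth_m": depth,
            "temp_C": temp,
            "sal_psu": sal,
            "chl_fl_mg_m3": chl_fl,
            "cdom_fl": cdom_fl,
            "bbp700_m1": bbp700,
        },
        columns=GLIDER_COLUMNS,
    )
    truth_df = pd.DataFrame(
        {
            "time": time,
            "lat": lat,
            "depth_m": depth,
            "temp_C_true": t_true,
            "sal_psu_true": s_true,
            "chl_true": chl_true,
            "is_day": np.asarray(is_day),
            "quench_factor": quench_factor,
        }
    )
    return records, truth_df, spike_masks


def synth_satellite_ensemble(
    transect: xr.Dataset,
    bands,
    noise_rel: float = 0.15,
    n: int = 100,
    seed: int = 0,
    coeffs: ModelCoefficients = DEFAULT,
) -> list[RrsSpectrum]:
    """Emulate a satellite Rrs ensemble from a gridded IOP transect.

    Forward-model Rrs at randomly sampled along-track columns, relabel
    each model wavelength to the nearest requested satellite band, and
    apply multiplicative lognormal noise of relative scale ``noise_rel``
    per band.  With ``noise_rel = 0`` each spectrum equals the
    forward-model Rrs of its column exactly.
    """
    rng = np.random.default_rng(seed)
    base = glider_rrs(transect, coeffs=coeffs)
    if not base:
        raise ValueError("transect has no complete surface columns")
    bands = np.atleast_1d(np.asarray(bands, dtype=float))
    model_lam = base[0].wavelengths
    # nearest model wavelength for each satellite band (no interpolation)
    nearest = np.array([model_lam[np.argmin(np.abs(model_lam - b))] for b in bands])

    picks = rng.integers(0, len(base), size=n)
    out = []
    for k in picks:
        src = base[k]
        vals = np.array([src.rrs[np.argmin(np.abs(model_lam - m))] for m in nearest])
        if noise_rel > 0:
            vals = vals * np.exp(noise_rel * rng.standard_normal(vals.size))
        out.append(RrsSpectrum(bands, vals, provenance="satellite"))
    return out
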