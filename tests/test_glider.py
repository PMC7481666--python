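import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glideropt import io as gio
from glideropt import model
from glideropt.coefficients import DEFAULT
from glideropt.glider import (
    along_track_distance,
    barnes_grid,
    chl_from_bbp,
    despike,
    grid_transect,
    hybrid_chl,
    split_profiles,
    transect_iops,
)
from glideropt.synth import FrontScenario, synth_glider_deployment

from conftest import NOISE_FREE, barnes_oracle


# ---------------------------------------------------------------------------
# despiking
# ---------------------------------------------------------------------------

class TestDespike:
    def test_constant_series_unmasked(self):
        cleaned, mask = despike(np.full(50, 3.2))
        assert not mask.any()
        np.testing.assert_array_equal(cleaned, np.full(50, 3.2))

    def test_single_outlier_masked_exactly(self):
        x = np.full(50, 1.0)
        x[25] = 100.0
        cleaned, mask = despike(x)
        assert mask[25]
        assert mask.sum() == 1
        assert np.isnan(cleaned[25])
        np.testing.assert_array_equal(cleaned[~mask], 1.0)

    def test_short_series_warns_and_passes_through(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="shorter"):
            cleaned, mask = despike(x, window=7)
        np.testing.assert_array_equal(cleaned, x)
        assert not mask.any()

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            despike(np.zeros(20), window=4)

    def test_synthetic_spike_mask_precision(self):
        # 1% spike rate, n_mad = 5, fixed seed; per-profile despiking
        scenario = FrontScenario(spike_rate=0.01, seed=2)
        records, _, masks = synth_glider_deployment(scenario)
        df = gio.process_records(records, gio.PipelineConfig())
        tp = fp = 0
        for col in ("chl_fl_mg_m3", "bbp700_m1"):
            found = np.isnan(df[col].to_numpy())
            true = masks[col]
            tp += int((found & true).sum())
            fp += int((found & ~true).sum())
        precision = tp / (tp + fp)
        assert precision >= 0.95

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        x = np.cumsum(rng.standard_normal(150)) * 0.1 + 0.05 * rng.standard_normal(150)
        x[rng.integers(0, 150, size=2)] += 40.0
        c1, _ = despike(x)
        c2, m2 = despike(c1)
        assert not m2.any()
        np.testing.assert_array_equal(np.isnan(c1), np.isnan(c2))
        np.testing.assert_array_equal(c1[~np.isnan(c1)], c2[~np.isnan(c2)])


# ---------------------------------------------------------------------------
# profile separation
# ---------------------------------------------------------------------------

def _records_from_depth(depth):
    n = len(depth)
    return pd.DataFrame(
        {
            "time": pd.date_range("2018-01-01", periods=n, freq="30s"),
            "depth_m": depth,
        }
    )


class TestSplitProfiles:
    def test_triangle_wave_counts(self):
        leg = np.linspace(0, 100, 25)
        depth = np.concatenate([np.concatenate([leg, leg[::-1][1:-1]]) for _ in range(10)])
        profiles = split_profiles(_records_from_depth(depth))
        assert len(profiles) == 20
        assert [p.direction for p in profiles[:4]] == ["dive", "climb", "dive", "climb"]

    def test_monotone_descent_single_profile(self):
        profiles = split_profiles(_records_from_depth(np.linspace(0, 200, 80)))
        assert len(profiles) == 1
        assert profiles[0].direction == "dive"

    def test_records_conserved(self):
        leg = np.linspace(0, 80, 20)
        depth = np.concatenate([leg, leg[::-1], leg, leg[::-1]])
        records = _records_from_depth(depth)
        profiles = split_profiles(records)
        assert sum(len(p) for p in profiles) == len(records)
        # contiguous, non-overlapping
        idx = np.concatenate([p.records.index.to_numpy() for p in profiles])
        np.testing.assert_array_equal(idx, records.index.to_numpy())

    def test_jittered_sawtooth_same_count(self):
        rng = np.random.default_rng(11)
        leg = np.linspace(0, 120, 30)
        clean = np.concatenate([np.concatenate([leg, leg[::-1]]) for _ in range(5)])
        jittered = clean + rng.uniform(-2.0, 2.0, clean.size)
        n_clean = len(split_profiles(_records_from_depth(clean), hysteresis=5.0))
        n_jit = len(split_profiles(_records_from_depth(np.abs(jittered)), hysteresis=5.0))
        assert n_jit == n_clean

    def test_empty_input(self):
        assert split_profiles(_records_from_depth(np.array([]))) == []


# ---------------------------------------------------------------------------
# chlorophyll estimation
# ---------------------------------------------------------------------------

class TestChlFromBbp:
    def test_unit_point(self):
        a700, _ = DEFAULT.bbp_table.interp(700.0)
        assert chl_from_bbp(a700) == pytest.approx(1.0)

    def test_round_trip(self):
        chl = np.linspace(0.1, 30.0, 200)
        rec = chl_from_bbp(model.bbp(700.0, chl))
        np.testing.assert_allclose(rec, chl, rtol=1e-10)

    def test_hand_evaluation(self):
        # Table row at 700 nm: A = 0.001, B = 0.683
        assert chl_from_bbp(0.001 * 10**0.683) == pytest.approx(10.0, rel=1e-10)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="bbp700"):
            chl_from_bbp(0.0)


class TestHybridChl:
    def test_fluorescence_regime(self):
        chl, flag = hybrid_chl(1.5, 0.005)
        assert chl == 1.5
        assert flag == "fluorescence"

    def test_boundary_inclusive(self):
        chl, flag = hybrid_chl(2.0, 0.005)
        assert chl == 2.0
        assert flag == "fluorescence"

    def test_backscatter_regime_forward_then_invert(self):
        chl, flag = hybrid_chl(5.0, model.bbp(700.0, 8.0))
        assert chl == pytest.approx(8.0, rel=1e-10)
        assert flag == "backscatter"

    def test_vectorized(self):
        chl_fl = np.array([0.5, 2.0, 3.0])
        bbp700 = model.bbp(700.0, np.array([1.0, 1.0, 6.0]))
        chl, flags = hybrid_chl(chl_fl, bbp700)
        np.testing.assert_allclose(chl, [0.5, 2.0, 6.0], rtol=1e-10)
        assert list(flags) == ["fluorescence", "fluorescence", "backscatter"]

    @given(chl_true=st.floats(min_value=2.2, max_value=30.0))
    @settings(max_examples=30)
    def test_left_inverse_in_backscatter_regime(self, chl_true):
        # quenched fluorescence still above threshold -> bbp route recovers truth
        chl, flag = hybrid_chl(2.01, model.bbp(700.0, chl_true))
        assert flag == "backscatter"
        assert chl == pytest.approx(chl_true, rel=1e-9)

    def test_negative_chl_fl_rejected(self):
        with pytest.raises(ValueError):
            hybrid_chl(-0.5, 0.01)


# ---------------------------------------------------------------------------
# Barnes objective analysis
# ---------------------------------------------------------------------------

class TestBarnesGrid:
    def test_constant_field_reproduced(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 30, 120)
        z = rng.uniform(0, 100, 120)
        v = np.full(120, 7.25)
        grid = barnes_grid(x, z, v, np.arange(0, 32, 2.0), np.arange(0, 105, 5.0))
        valid = np.isfinite(grid)
        assert valid.any()
        np.testing.assert_allclose(grid[valid], 7.25, atol=1e-9)

    def test_single_observation_peak_at_nearest_node(self):
        x_grid = np.arange(0, 20, 2.0)
        z_grid = np.arange(0, 50, 5.0)
        grid = barnes_grid([7.9], [21.0], [3.0], x_grid, z_grid, passes=1)
        j = int(np.argmin(np.abs(x_grid - 7.9)))
        i = int(np.argmin(np.abs(z_grid - 21.0)))
        assert grid[i, j] == np.nanmax(grid)

    def test_empty_input_all_missing(self):
        grid = barnes_grid([], [], [], np.arange(0, 10, 2.0), np.arange(0, 20, 5.0))
        assert np.all(np.isnan(grid))

    def test_far_cells_missing(self):
        grid = barnes_grid(
            [0.0], [0.0], [1.0],
            np.arange(0, 200, 2.0), np.arange(0, 10, 5.0),
            radii=(10.0, 10.0), cutoff=3.0,
        )
        # cells beyond 3 radii (30 km) from the lone observation are missing
        assert np.isnan(grid[0, -1])
        assert np.isfinite(grid[0, 0])

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        n = 60
        x = rng.uniform(0, 40, n)
        z = rng.uniform(0, 80, n)
        v = np.sin(x / 8.0) + 0.02 * z + rng.normal(0, 0.05, n)
        x_grid = np.arange(0, 42, 2.0)
        z_grid = np.arange(0, 85, 5.0)
        kwargs = dict(radii=(8.0, 15.0), passes=3, gamma=0.4, cutoff=3.0)
        ours = barnes_grid(x, z, v, x_grid, z_grid, **kwargs)
        ref = barnes_oracle(x, z, v, x_grid, z_grid, **kwargs)
        np.testing.assert_allclose(ours, ref, atol=1e-9)

    def test_second_pass_reduces_error_on_smooth_field(self):
        # brute-force-verified successive correction should sharpen a plane
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 30, 400)
        z = rng.uniform(0, 60, 400)
        v = 0.3 * x + 0.1 * z
        x_grid = np.arange(2, 28, 2.0)
        z_grid = np.arange(5, 55, 5.0)
        truth = 0.3 * x_grid[None, :] + 0.1 * z_grid[:, None]
        g1 = barnes_grid(x, z, v, x_grid, z_grid, radii=(6.0, 12.0), passes=1)
        g2 = barnes_grid(x, z, v, x_grid, z_grid, radii=(6.0, 12.0), passes=2)
        rms1 = np.sqrt(np.nanmean((g1 - truth) ** 2))
        rms2 = np.sqrt(np.nanmean((g2 - truth) ** 2))
        assert rms2 < rms1

    def test_parameter_validation(self):
        xg, zg = np.arange(0, 4, 2.0), np.arange(0, 10, 5.0)
        with pytest.raises(ValueError, match="passes"):
            barnes_grid([0], [0], [1], xg, zg, passes=0)
        with pytest.raises(ValueError, match="gamma"):
            barnes_grid([0], [0], [1], xg, zg, gamma=1.5)
        with pytest.raises(ValueError, match="radii"):
            barnes_grid([0], [0], [1], xg, zg, radii=(0.0, 5.0))


def test_along_track_distance_monotone_and_scaled():
    lat = np.linspace(74.8, 75.8, 50)
    lon = np.full(50, 30.0)
    d = along_track_distance(lat, lon)
    assert d[0] == 0.0
    assert np.all(np.diff(d) > 0)
    # one degree of latitude is ~111 km
    assert d[-1] == pytest.approx(111.2, rel=0.01)


# ---------------------------------------------------------------------------
# gridded transects and IOP fields
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_transect():
    scenario = FrontScenario(noise=dict(NOISE_FREE), seed=3)
    records, _, _ = synth_glider_deployment(
        scenario, n_profiles=10, samples_per_profile=30, dive_depth=100.0,
        end_lat=76.4,
    )
    records = records.assign(chl=records["chl_fl_mg_m3"])
    return grid_transect(records)


class TestGridTransect:
    def test_grid_spacing(self, small_transect):
        assert np.allclose(np.diff(small_transect["along_track_km"]), 2.0)
        assert np.allclose(np.diff(small_transect["depth_m"]), 5.0)

    def test_missing_cells_are_nan_not_zero(self):
        records = pd.DataFrame(
            {
                "time": pd.date_range("2018-01-01", periods=10, freq="1min"),
                "lat": np.linspace(75.0, 75.01, 10),
                "lon": np.full(10, 30.0),
                "depth_m": np.linspace(0, 10, 10),
                "temp_C": np.full(10, 4.0),
                "sal_psu": np.full(10, 34.0),
                "bbp700_m1": np.full(10, 0.002),
            }
        )
        ds = grid_transect(records, fields={"salinity": records["sal_psu"].to_numpy()})
        # a 1 km track cannot constrain cells at 100+ m depth
        assert ds["salinity"].shape[0] >= 1


class TestTransectIOPs:
    def test_requires_chl_and_salinity(self, small_transect):
        bare = small_transect.drop_vars(["chl"])
        with pytest.raises(ValueError, match="chl"):
            transect_iops(bare)

    def test_cellwise_equality_with_direct_model(self, small_transect):
        ds = transect_iops(small_transect, wavelengths=[440.0, 555.0])
        chl = ds["chl"].values
        sal = ds["salinity"].values
        temp = ds["temperature"].values
        i, j = 2, 5
        assert np.isfinite(chl[i, j])
        bundle = model.total_iops([440.0, 555.0], chl[i, j], sal[i, j], temp[i, j])
        got = ds["a_total"].values[:, i, j]
        np.testing.assert_allclose(got, bundle.a_total.values, rtol=1e-12)
        np.testing.assert_allclose(
            ds["bb_total"].values[:, i, j], bundle.bb_total.values, rtol=1e-12
        )

    def test_uniform_fields_give_uniform_iops(self):
        ds = grid_transect(
            pd.DataFrame(
                {
                    "time": pd.date_range("2018-01-01", periods=400, freq="30s"),
                    "lat": np.linspace(75.0, 75.3, 400),
                    "lon": np.full(400, 30.0),
                    "depth_m": np.tile(np.linspace(0, 90, 40), 10),
                    "temp_C": np.full(400, 4.0),
                    "sal_psu": np.full(400, 34.0),
                    "chl": np.full(400, 1.5),
                    "bbp700_m1": np.full(400, 0.002),
                }
            ),
            fields=None,
        )
        out = transect_iops(ds, wavelengths=[488.0])
        vals = out["a_total"].values[0]
        finite = vals[np.isfinite(vals)]
        assert finite.size > 10
        np.testing.assert_allclose(finite, finite.flat[0], rtol=1e-9)

    def test_missing_cells_propagate(self, small_transect):
        ds = transect_iops(small_transect, wavelengths=[440.0])
        missing = ~np.isfinite(ds["chl"].values)
        if missing.any():
            assert np.all(~np.isfinite(ds["a_total"].values[0][missing]))

    def test_front_contrast_in_a_nw(self, noise_free_scenario, noise_free_deployment):
        records, _, _ = noise_free_deployment
        records = records.assign(chl=records["chl_fl_mg_m3"])
        ds = transect_iops(grid_transect(records), wavelengths=[440.0])
        a_nw = ds["a_nw"].values[0]
        depth = ds["depth_m"].values
        top = depth <= 50.0
        x = ds["along_track_km"].values
        south = x < x.max() * 0.25
        north = x > x.max() * 0.75
        a_south = np.nanmean(a_nw[np.ix_(top, south)])
        a_north = np.nanmean(a_nw[np.ix_(top, north)])
        assert a_north > a_south
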