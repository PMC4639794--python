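"""Anomalies, box means, isotherm location, EOF and the PF regression."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from divepop import ocean, synth


def toy_field(values, lats=None, lons=None, years=None, months=(2, 3)):
    """Build a small SST dataset; `values` broadcast to (time, lat, lon)."""
    lats = np.array([-52.0, -48.0, -44.0, -30.0]) if lats is None else lats
    lons = np.array([50.0, 52.0, 54.0]) if lons is None else lons
    years = range(2000, 2006) if years is None else years
    times, cubes = [], []
    v = np.asarray(values, dtype=float)
    k = 0
    for y in years:
        for m in months:
            times.append(np.datetime64(f"{y}-{m:02d}-15"))
            cubes.append(np.broadcast_to(v[k] if v.ndim == 3 else v,
                                         (lats.size, lons.size)).copy())
            k += 1 if v.ndim == 3 else 0
    da = xr.DataArray(np.stack(cubes), dims=("time", "lat", "lon"),
                      coords={"time": times, "lat": lats, "lon": lons},
                      name="sst")
    return da.to_dataset()


class TestAnomalies:
    def test_constant_field_zero_anomalies(self):
        ds = toy_field(np.full((4, 3), 7.0))
        assert np.allclose(ocean.anomalies(ds).values, 0.0)

    def test_single_warm_year_mean_removal_algebra(self):
        n_years = 6
        cubes = np.zeros((n_years * 2, 4, 3))
        cubes[0:2] += 1.0  # first year +1 degC in both months
        ds = toy_field(cubes)
        a = ocean.anomalies(ds)
        expected = 1.0 * (1 - 1 / n_years)
        assert np.allclose(a.isel(time=0).values, expected)
        assert np.allclose(a.isel(time=2).values, -1.0 / n_years)

    def test_pure_seasonal_cycle_absorbed(self):
        cubes = np.zeros((12, 4, 3))
        cubes[0::2] = 3.0  # month-2 value
        cubes[1::2] = 9.0  # month-3 value
        ds = toy_field(cubes)
        assert np.allclose(ocean.anomalies(ds).values, 0.0)

    def test_missing_baseline_month_rejected(self):
        ds = toy_field(np.full((4, 3), 7.0))
        with pytest.raises(ValueError, match="baseline"):
            ocean.anomalies(ds, baseline_years=(1990, 1995))


class TestBoxSSTA:
    def test_uniform_anomaly(self):
        ds = toy_field(np.full((4, 3), 2.0))
        a = ocean.anomalies(ds) + 0.5
        s = ocean.box_ssta(a, lat_range=(-53, -47), lon_range=(49, 55))
        assert np.allclose(s.values, 0.5)

    def test_latitude_linear_anomaly_weighted_mean(self):
        lats = np.array([-52.0, -50.0, -48.0])
        ds = toy_field(np.zeros((3, 3)), lats=lats)
        a = ocean.anomalies(ds) + xr.DataArray(lats + 50.0, coords={"lat": lats})
        s = ocean.box_ssta(a, lat_range=(-53, -47), lon_range=(49, 55))
        w = np.cos(np.deg2rad(lats))
        expected = np.sum((lats + 50.0) * w) / w.sum()
        assert np.allclose(s.values, expected)

    def test_empty_box_rejected(self):
        ds = toy_field(np.full((4, 3), 2.0))
        with pytest.raises(ValueError):
            ocean.box_ssta(ocean.anomalies(ds), lat_range=(10, 20))


class TestLocatePF:
    def test_linear_meridional_profile_exact_crossing(self):
        lats = np.arange(-58.0, -40.0, 2.0)
        prof = 9.0 + 0.5 * (lats + 44.0)  # 5 degC exactly at -52
        ds = toy_field(np.broadcast_to(prof[:, None], (lats.size, 3)),
                       lats=lats)
        pf = ocean.locate_pf(ds, months=(2, 3))
        assert np.allclose(pf.latitude, -52.0)

    def test_uniform_warm_field_error(self):
        ds = toy_field(np.full((4, 3), 10.0))
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                ocean.locate_pf(ds, months=(2, 3))

    def test_equivariance_under_uniform_shift(self):
        lats = np.arange(-58.0, -40.0, 2.0)
        rng = np.random.default_rng(0)
        prof = 9.0 + 0.5 * (lats + 44.0)
        cubes = (np.broadcast_to(prof[:, None], (12, lats.size, 3))
                 + rng.normal(0, 0.1, (12, lats.size, 3)))
        ds = toy_field(cubes, lats=lats)
        shifted = ds + 1.0
        a = ocean.locate_pf(shifted, isotherm=5.0, months=(2, 3))
        b = ocean.locate_pf(ds, isotherm=4.0, months=(2, 3))
        assert np.allclose(a.latitude, b.latitude)

    def test_planted_coupling_recovered(self):
        ds, truth = synth.gen_sst_fields(synth.SSTTruth(noise_sd=0.0),
                                         n_years=12, seed=0)
        pf = ocean.locate_pf(ds)
        # exact where the crossing lies between polar (noise-free) rows;
        # crossings north of 52 S touch one row carrying the domain noise
        assert np.allclose(pf.latitude, truth.pf_lat_series, atol=0.12)
        assert np.median(np.abs(pf.latitude - truth.pf_lat_series)) < 0.01


class TestEOF:
    def test_rank_one_field(self):
        lats = np.arange(-48.0, -10.0, 2.0)
        lons = np.arange(-50.0, 150.0, 10.0)
        rng = np.random.default_rng(1)
        pattern = rng.normal(0, 1, (lats.size, lons.size))
        series = rng.normal(0, 1, 8)
        cubes = np.repeat(series[:, None, None] * pattern[None], 2, axis=0)
        ds = toy_field(cubes, lats=lats, lons=lons, years=range(2000, 2008))
        idx = ocean.eof_leading(ocean.anomalies(ds))
        assert idx.explained_variance == pytest.approx(1.0, abs=1e-9)
        r = np.corrcoef(idx.pc, series)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_leading_mode_is_larger_planted_mode(self):
        lats = np.arange(-48.0, -10.0, 2.0)
        lons = np.arange(-50.0, 150.0, 10.0)
        rng = np.random.default_rng(2)
        p1 = rng.normal(0, 1, (lats.size, lons.size))
        p2 = rng.normal(0, 1, (lats.size, lons.size))
        p2 -= p1 * np.sum(p1 * p2) / np.sum(p1 ** 2)  # orthogonal
        s1 = rng.normal(0, 2.0, 10)
        s2 = rng.normal(0, 0.5, 10)
        s2 -= s1 * (s1 @ s2) / (s1 @ s1)
        cubes = np.repeat((s1[:, None, None] * p1[None]
                           + s2[:, None, None] * p2[None]), 2, axis=0)
        ds = toy_field(cubes, lats=lats, lons=lons, years=range(2000, 2010))
        idx = ocean.eof_leading(ocean.anomalies(ds))
        assert abs(np.corrcoef(idx.pc, s1)[0, 1]) > 0.99

    def test_full_expansion_reconstructs(self):
        ds, _ = synth.gen_sst_fields(synth.SSTTruth(), n_years=8, seed=3)
        err = ocean.eof_reconstruction(ocean.anomalies(ds))
        assert err < 1e-8

    def test_explained_variance_invariant_to_year_relabeling(self):
        ds, _ = synth.gen_sst_fields(synth.SSTTruth(), n_years=10, seed=4)
        a = ocean.anomalies(ds)
        idx = ocean.eof_leading(a)
        # reverse the time axis: same sample covariance
        rev = a.copy()
        rev = rev.assign_coords(time=a.time.values[::-1]).sortby("time")
        idx2 = ocean.eof_leading(rev)
        assert idx.explained_variance == pytest.approx(idx2.explained_variance,
                                                       abs=1e-10)

    def test_too_few_years_rejected(self):
        ds, _ = synth.gen_sst_fields(synth.SSTTruth(), n_years=10, seed=0)
        a = ocean.anomalies(ds).isel(time=slice(0, 4))
        with pytest.raises(ValueError, match="3 years"):
            ocean.eof_leading(a)


class TestPFSlope:
    def test_noiseless_linear_regression(self):
        years = np.arange(2000, 2014)
        ssta = pd.Series(np.linspace(-1, 1, years.size), index=years)
        anom_deg = 130.0 * ssta.values / ocean.KM_PER_DEG_LAT
        pf = ocean.PFSeries(year=years, latitude=-52.0 - anom_deg,
                            anomaly_deg=anom_deg,
                            distance_km=np.full(years.size, 600.0))
        res = ocean.pf_ssta_slope(pf, ssta)
        assert res["slope_km_per_degC"] == pytest.approx(130.0)
        assert res["r2"] == pytest.approx(1.0)
        assert res["df"] == (1, years.size - 2)

    def test_zero_variance_rejected(self):
        years = np.arange(2000, 2010)
        pf = ocean.PFSeries(year=years, latitude=np.full(10, -52.0),
                            anomaly_deg=np.zeros(10),
                            distance_km=np.full(10, 600.0))
        with pytest.raises(ValueError):
            ocean.pf_ssta_slope(pf, pd.Series(np.zeros(10), index=years))

    def test_generated_coupling_confidence_interval(self):
        slopes = []
        for seed in range(5):
            ds, _ = synth.gen_sst_fields(synth.SSTTruth(), n_years=20, seed=seed)
            a = ocean.anomalies(ds)
            res = ocean.pf_ssta_slope(ocean.locate_pf(ds), ocean.box_ssta(a))
            slopes.append(res["slope_km_per_degC"])
        assert np.mean(slopes) == pytest.approx(130.0, abs=6.0)
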