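"""Gridded-SST products: anomalies, box-mean SSTA, polar-front latitude
from the 5 degC surface isotherm, the leading-EOF dipole index, and the
front-shift-per-degree regression.

Conventions: latitudes in degrees (southern hemisphere negative),
longitudes in degrees east.  The polar front (PF) is operationalized as
the summer northern limit of the 5 degC surface isotherm; its anomaly is
reported with positive = southward displacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import xarray as xr

from .synth import KM_PER_DEG_LAT

#: default PF sector and covariate box (degrees; lat negative = south)
PF_SECTOR = (50.0, 54.0)
SSTA_BOX_LAT = (-53.0, -47.0)
SSTA_BOX_LON = (49.0, 55.0)
SAIOD_DOMAIN_LAT = (-50.0, -10.0)
SAIOD_DOMAIN_LON = (-50.0, 150.0)
COLONY_LAT, COLONY_LON = -46.43, 51.86  # Possession Island


@dataclass
class PFSeries:
    year: np.ndarray
    latitude: np.ndarray  # sector-mean northernmost isotherm latitude (deg)
    anomaly_deg: np.ndarray  # vs period mean, positive = south
    distance_km: np.ndarray  # great-circle distance from the colony


@dataclass
class SAIODIndex:
    year: np.ndarray
    pc: np.ndarray  # standardized leading-PC amplitude, unit variance
    explained_variance: float  # fraction in (0, 1]
    pattern: xr.DataArray  # spatial loading (weighted EOF)


def anomalies(field: xr.Dataset | xr.DataArray,
              baseline_years: tuple[int, int] | None = None) -> xr.DataArray:
    """Per-cell, per-calendar-month climatology removal."""
    sst = field["sst"] if isinstance(field, xr.Dataset) else field
    years = sst["time"].dt.year
    if baseline_years is None:
        base = sst
    else:
        y0, y1 = baseline_years
        base = sst.sel(time=(years >= y0) & (years <= y1))
        if base.time.size == 0:
            raise ValueError("baseline period outside the record")
    months_all = set(np.unique(sst["time"].dt.month.values))
    months_base = set(np.unique(base["time"].dt.month.values))
    if not months_all <= months_base:
        raise ValueError(
            f"months {sorted(months_all - months_base)} missing from baseline")
    clim = base.groupby("time.month").mean("time")
    return (sst.groupby("time.month") - clim).drop_vars("month")


def box_ssta(anoms: xr.DataArray, lat_range=SSTA_BOX_LAT,
             lon_range=SSTA_BOX_LON, months=(2, 3)) -> pd.Series:
    """Area-weighted (cos latitude) yearly mean anomaly over a box."""
    sel = anoms.sel(lat=slice(*sorted(lat_range)), lon=slice(*sorted(lon_range)))
    if sel.lat.size == 0 or sel.lon.size == 0:
        raise ValueError("box does not intersect the grid")
    sel = sel.sel(time=sel["time"].dt.month.isin(list(months)))
    w = np.cos(np.deg2rad(sel.lat))
    yearly = sel.weighted(w).mean(("lat", "lon")).groupby("time.year").mean()
    return yearly.to_series()


def _haversine_km(lat1, lon1, lat2, lon2) -> float:
    rl1, rl2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dlat = rl2 - rl1
    dlon = np.deg2rad(lon2 - lon1)
    a = np.sin(dlat / 2) ** 2 + np.cos(rl1) * np.cos(rl2) * np.sin(dlon / 2) ** 2
    return float(2 * 6371.0 * np.arcsin(np.sqrt(a)))


def locate_pf(field: xr.Dataset | xr.DataArray, isotherm: float = 5.0,
              sector=PF_SECTOR, months=(1, 2, 3),
              colony=(COLONY_LAT, COLONY_LON)) -> PFSeries:
    """Latitude of the northernmost isotherm crossing, per year.

    For each longitude column in the sector the summer-mean SST profile is
    scanned from north to south; the first adjacent latitude pair bracketing
    the isotherm gives the crossing by linear interpolation.  Columns that
    never cross are skipped with a warning; the sector mean over columns is
    returned per year, with its anomaly (positive = south) and the
    great-circle distance from the colony.
    """
    sst = field["sst"] if isinstance(field, xr.Dataset) else field
    sel = sst.sel(lon=slice(*sector))
    sel = sel.sel(time=sel["time"].dt.month.isin(list(months)))
    if sel.lon.size == 0:
        raise ValueError("sector does not intersect the grid")
    summer = sel.groupby("time.year").mean("time")
    lats = summer.lat.values
    order = np.argsort(lats)[::-1]  # north (max lat) first
    years = summer.year.values
    pf_lat = np.full(years.size, np.nan)
    for iy in range(years.size):
        crossings = []
        for ilon in range(summer.lon.size):
            prof = summer.isel(year=iy, lon=ilon).values[order]
            la = lats[order]
            found = None
            for k in range(prof.size - 1):
                t0, t1 = prof[k], prof[k + 1]
                if (t0 - isotherm) * (t1 - isotherm) <= 0 and t0 != t1:
                    frac = (t0 - isotherm) / (t0 - t1)
                    found = la[k] + frac * (la[k + 1] - la[k])
                    break
            if found is None:
                warnings.warn(
                    f"isotherm {isotherm} degC never crossed at lon "
                    f"{float(summer.lon[ilon]):.1f}; column skipped")
            else:
                crossings.append(found)
        if not crossings:
            raise ValueError("isotherm absent from every sector column")
        pf_lat[iy] = np.mean(crossings)
    anomaly = pf_lat.mean() - pf_lat  # southward (lat decrease) positive
    dist = np.array([_haversine_km(colony[0], colony[1], la, colony[1])
                     for la in pf_lat])
    return PFSeries(year=years, latitude=pf_lat, anomaly_deg=anomaly,
                    distance_km=dist)


def eof_leading(anoms: xr.DataArray, domain_lat=SAIOD_DOMAIN_LAT,
                domain_lon=SAIOD_DOMAIN_LON, months=(2, 3)) -> SAIODIndex:
    """Leading EOF/PC of seasonal-mean anomalies over a domain.

    Cells are weighted by sqrt(cos latitude); the year x cell matrix is
    centred over years and decomposed by SVD (covariance-based PCA).  The
    PC is standardized to unit variance; explained variance is the leading
    eigenvalue over the trace.  Sign convention: a positive index goes
    with positive loadings in the southwest of the two basins.
    """
    sel = anoms.sel(lat=slice(*sorted(domain_lat)), lon=slice(*sorted(domain_lon)))
    if sel.lat.size == 0 or sel.lon.size == 0:
        raise ValueError("domain does not intersect the grid")
    sel = sel.sel(time=sel["time"].dt.month.isin(list(months)))
    seasonal = sel.groupby("time.year").mean("time")
    years = seasonal.year.values
    if years.size < 3:
        raise ValueError("need at least 3 years for an EOF")
    w = np.sqrt(np.cos(np.deg2rad(seasonal.lat.values)))
    M = (seasonal.values * w[None, :, None]).reshape(years.size, -1)
    good = np.all(np.isfinite(M), axis=0)
    Mg = M[:, good]
    Mg = Mg - Mg.mean(axis=0)
    U, s, Vt = np.linalg.svd(Mg, full_matrices=False)
    explained = float(s[0] ** 2 / np.sum(s ** 2))
    pc = U[:, 0] * s[0]
    pat_flat = np.full(M.shape[1], np.nan)
    pat_flat[good] = Vt[0]
    pat = pat_flat.reshape(seasonal.shape[1:]) / w[:, None]  # undo weighting
    pattern = xr.DataArray(pat, dims=("lat", "lon"),
                           coords={"lat": seasonal.lat, "lon": seasonal.lon})
    # sign: positive loadings in the SW quadrant of each basin
    sw = pattern.sel(lat=slice(-45.0, -30.0))
    sw_mean = float(np.nanmean(np.concatenate([
        sw.sel(lon=slice(-50.0, -5.0)).values.ravel(),
        sw.sel(lon=slice(55.0, 100.0)).values.ravel()])))
    if sw_mean < 0:
        pc, pattern = -pc, -pattern
    pc = pc / pc.std(ddof=0)
    return SAIODIndex(year=years, pc=pc, explained_variance=explained,
                      pattern=pattern)


def eof_reconstruction(anoms: xr.DataArray, **kwargs) -> float:
    """Max reconstruction error of the full EOF expansion (diagnostic)."""
    sel = anoms.sel(lat=slice(*sorted(kwargs.get("domain_lat", SAIOD_DOMAIN_LAT))),
                    lon=slice(*sorted(kwargs.get("domain_lon", SAIOD_DOMAIN_LON))))
    sel = sel.sel(time=sel["time"].dt.month.isin(list(kwargs.get("months", (2, 3)))))
    seasonal = sel.groupby("time.year").mean("time")
    w = np.sqrt(np.cos(np.deg2rad(seasonal.lat.values)))
    M = (seasonal.values * w[None, :, None]).reshape(seasonal.shape[0], -1)
    M = M - M.mean(axis=0)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    return float(np.max(np.abs(M - (U * s) @ Vt)))


def pf_ssta_slope(pf: PFSeries, ssta: pd.Series) -> dict:
    """OLS of PF displacement (km, southward positive) on box SSTA."""
    years = np.intersect1d(pf.year, ssta.index.values)
    if years.size < 5:
        raise ValueError("need at least 5 paired years")
    disp = pd.Series(pf.anomaly_deg * KM_PER_DEG_LAT, index=pf.year).loc[years]
    x = ssta.loc[years]
    if float(np.var(x)) == 0:
        raise ValueError("zero SSTA variance")
    X = sm.add_constant(x.to_numpy())
    res = sm.OLS(disp.to_numpy(), X).fit()
    return {"slope_km_per_degC": float(res.params[1]),
            "intercept_km": float(res.params[0]),
            "r2": float(res.rsquared), "F": float(res.fvalue),
            "p": float(res.f_pvalue),
            "df": (int(res.df_model), int(res.df_resid)),
            "n": int(years.size)}
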