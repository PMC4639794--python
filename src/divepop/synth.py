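"""Seeded synthetic-data generators for every input the pipeline consumes.

Each generator returns both the data product and the ground truth planted
in it, so detectors and fitters downstream can be checked by round-trip.
All randomness flows through a single integer seed; regeneration with the
same seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .records import DepthRecord, TemperatureRecord

KM_PER_DEG_LAT = 111.2  # meridian arc length per degree of latitude


# ---------------------------------------------------------------------------
# dive / oesophageal generators
# ---------------------------------------------------------------------------

@dataclass
class DivePlan:
    """Blueprint for one planted dive."""

    start: float  # s, dive start (leaves surface)
    max_depth: float  # m
    n_wiggles: int = 0
    n_steps: int = 0
    descent_rate: float = 1.3  # m/s, the species' typical vertical speed
    ascent_rate: float = 1.3  # m/s
    bottom_duration: float = 72.0  # s, time at the bottom excluding wiggles
    post_surface: float = 120.0  # s at the surface after the dive

    def __post_init__(self) -> None:
        if self.max_depth <= 0:
            raise ValueError("max_depth must be positive")
        if self.n_wiggles < 0 or self.n_steps < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class Ingestion:
    time: float  # s, must fall inside a dive's bottom phase
    mass: float  # g
    drop_rate: float | None = None  # degC/s; None uses the generator default

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError("prey mass must be >= 0")


@dataclass
class DiveTruth:
    """Planted trip-level truth: dives plus ingestion events."""

    dives: list  # list[DivePlan]
    ingestions: list = field(default_factory=list)  # list[Ingestion]


def _build_dive_samples(plan: DivePlan, dt: float,
                        step_speed: float = 0.2,
                        step_duration: float = 6.0,
                        wiggle_frac: float = 0.12):
    """Per-sample depth increments for one dive.

    All segments are built sample-by-sample so that sampled vertical speeds
    equal the planted ones exactly (no blurring at segment boundaries).
    """
    depths = []
    d = 0.0
    # --- descent, with n_steps slow plateaus interleaved ---
    n_step_samp = max(2, int(round(step_duration / dt)))
    step_depth_total = plan.n_steps * n_step_samp * step_speed * dt
    fast_depth = plan.max_depth - step_depth_total
    if fast_depth <= 0:
        raise ValueError("dive too shallow for the requested number of steps")
    n_fast = max(plan.n_steps + 1, int(np.ceil(fast_depth / (plan.descent_rate * dt))))
    fast_inc = fast_depth / n_fast  # per-sample increment, close to rate*dt
    if fast_inc / dt <= 0.35:
        raise ValueError("descent rate too close to the step-speed threshold")
    # split fast samples into n_steps+1 runs
    runs = np.full(plan.n_steps + 1, n_fast // (plan.n_steps + 1), dtype=int)
    runs[: n_fast % (plan.n_steps + 1)] += 1
    for k, run in enumerate(runs):
        for _ in range(run):
            d += fast_inc
            depths.append(d)
        if k < plan.n_steps:
            for _ in range(n_step_samp):
                d += step_speed * dt
                depths.append(d)
    d = depths[-1] = plan.max_depth  # guard against rounding residue
    # --- bottom, with n_wiggles planted reversals ---
    amp = min(8.0, wiggle_frac * plan.max_depth)
    n_flat = max(1, int(round(plan.bottom_duration / dt)))
    n_wig_samp = 4  # 2 up (depth decreasing), 2 down
    flat_runs = np.full(plan.n_wiggles + 1, n_flat // (plan.n_wiggles + 1), dtype=int)
    flat_runs[: n_flat % (plan.n_wiggles + 1)] += 1
    flat_runs = np.maximum(flat_runs, 1)  # >=1 flat sample separates wiggles
    for k, run in enumerate(flat_runs):
        for _ in range(run):
            depths.append(plan.max_depth)
        if k < plan.n_wiggles:
            half = n_wig_samp // 2
            for j in range(half):  # rising toward surface: speed < 0
                depths.append(plan.max_depth - amp * (j + 1) / half)
            for j in range(half - 1):  # back down: speed > 0
                depths.append(plan.max_depth - amp * (half - 1 - j) / half)
            depths.append(plan.max_depth)
    # --- ascent ---
    n_asc = max(1, int(np.ceil(plan.max_depth / (plan.ascent_rate * dt))))
    asc_inc = plan.max_depth / n_asc
    d = plan.max_depth
    for _ in range(n_asc):
        d -= asc_inc
        depths.append(max(d, 0.0))
    depths[-1] = 0.0
    return np.asarray(depths)


def gen_dive_record(plan: DiveTruth, sampling_interval: float, seed: int = 0,
                    noise_sd: float = 0.0) -> tuple[DepthRecord, DiveTruth]:
    """Render a planted dive plan into a sampled depth trace.

    Parameters
    ----------
    plan : DiveTruth
        Dives (non-overlapping) and ingestion events.
    sampling_interval : float
        Seconds between samples; loggers sampled every 1, 2 or 5 s.
    noise_sd : float
        Optional white depth noise (m).  Zero keeps planted counts exact.
    """
    if sampling_interval not in (1, 2, 5):
        raise ValueError("sampling_interval must be 1, 2 or 5 s")
    dt = float(sampling_interval)
    dives = sorted(plan.dives, key=lambda p: p.start)
    rng = np.random.default_rng(seed)

    segments = []
    end_time = 0.0
    for dv in dives:
        start = round(dv.start / dt) * dt
        if start < end_time:
            raise ValueError(
                f"overlapping dives in plan: dive at t={dv.start:.0f}s starts "
                f"before the previous dive ends at t={end_time:.0f}s")
        samples = _build_dive_samples(dv, dt)
        segments.append((start, samples))
        end_time = start + len(samples) * dt + dv.post_surface

    total_t = end_time + 60.0
    n = int(np.ceil(total_t / dt)) + 1
    depth = np.zeros(n)
    time = np.arange(n) * dt
    for start, samples in segments:
        i0 = int(round(start / dt)) + 1
        depth[i0: i0 + samples.size] = samples
    if noise_sd > 0:
        depth = np.clip(depth + rng.normal(0.0, noise_sd, n), 0.0, None)
    return DepthRecord(time=time, depth=depth), plan


def random_trip_plan(n_days: float = 7.0, depth_range=(50.0, 306.0),
                     seed: int = 0, mean_prey_per_dive: float = 0.8,
                     front_ratio: float = 2.0,
                     prey_mass_range=(1.8, 25.0)) -> DiveTruth:
    """Random multi-day foraging trip within the observed diving-depth range.

    The second half of the trip stands in for time spent at the polar
    front, where the per-dive capture rate is `front_ratio` times the
    transit rate (default twice, matching the contrast the trip emulates).
    """
    rng = np.random.default_rng(seed)
    lo, hi = depth_range
    dives, ingestions = [], []
    t = 300.0
    horizon = n_days * 86400.0
    while t < horizon:
        depth = float(rng.uniform(lo, hi))
        plan = DivePlan(start=t, max_depth=depth,
                        n_wiggles=int(rng.integers(0, 6)),
                        n_steps=int(rng.integers(0, 3)),
                        bottom_duration=float(rng.uniform(60.0, 80.0)),
                        post_surface=float(rng.uniform(90.0, 200.0)))
        dur_est = 2 * depth / 1.3 + plan.bottom_duration + plan.n_wiggles * 10 + 40
        # place ingestions in the (approximate) bottom phase
        rate = mean_prey_per_dive * (front_ratio if t > horizon / 2 else 1.0)
        n_prey = rng.poisson(rate)
        b0 = t + depth / 1.3 + 5
        b1 = b0 + plan.bottom_duration - 10
        for ts in np.sort(rng.uniform(b0, b1, n_prey)):
            ingestions.append(Ingestion(time=float(ts),
                                        mass=float(rng.uniform(*prey_mass_range))))
        dives.append(plan)
        t += dur_est + plan.post_surface
    return DiveTruth(dives=dives, ingestions=ingestions)


def gen_oesophageal_trace(depth: DepthRecord, ingestions, seed: int = 0,
                          baseline: float = 38.0, drop_rate: float = 0.10,
                          amplitude_per_g: float = 0.1,
                          recovery_tau: float = 60.0,
                          min_detectable_mass: float = 1.8,
                          noise_sd: float = 0.0) -> tuple[TemperatureRecord, pd.DataFrame]:
    """Oesophageal temperature with an exponential drop/recovery per ingestion.

    Each ingestion of mass m >= `min_detectable_mass` grams produces a linear
    decline at `drop_rate` deg C/s down to an amplitude of `amplitude_per_g*m`
    deg C below the running baseline, followed by exponential recovery with
    time constant `recovery_tau`.  Smaller prey leave no signal (below the
    sensor's sensitivity floor, calibrated on captive birds at 1.8 g).
    Returns the trace and a truth table (onset, mass, rate, amplitude).
    """
    rng = np.random.default_rng(seed)
    dt = depth.dt
    n = depth.time.size
    t = depth.time
    temp = np.full(n, baseline)
    rows = []
    for ev in ingestions:
        rate = getattr(ev, "drop_rate", None) or drop_rate
        if ev.mass < 0:
            raise ValueError("negative prey mass")
        if ev.mass < min_detectable_mass:
            continue
        amp = amplitude_per_g * ev.mass
        i0 = int(round(ev.time / dt))
        if i0 >= n - 1:
            continue
        n_drop = max(1, int(np.ceil(amp / (rate * dt))))
        drop_inc = amp / n_drop
        j = np.arange(i0 + 1, min(i0 + 1 + n_drop, n))
        contrib = np.zeros(n)
        contrib[j] = drop_inc * (j - i0)
        k = np.arange(i0 + 1 + n_drop, n)
        if k.size:
            contrib[k] = amp * np.exp(-(t[k] - t[i0 + n_drop]) / recovery_tau)
        temp -= contrib
        rows.append({"onset": i0 * dt, "mass": ev.mass,
                     "drop_rate": drop_inc / dt, "amplitude": amp,
                     "drop_duration": n_drop * dt})
    if noise_sd > 0:
        temp = temp + rng.normal(0.0, noise_sd, n)
    truth = pd.DataFrame(rows, columns=["onset", "mass", "drop_rate",
                                        "amplitude", "drop_duration"])
    return TemperatureRecord(time=t.copy(), temperature=temp), truth


# ---------------------------------------------------------------------------
# Gompertz population series
# ---------------------------------------------------------------------------

@dataclass
class GompertzTruth:
    """Parameters of the stochastic Gompertz state-space model.

    x_{t+1} = x_t + r - b*x_t + c*z_t + eps_t,  eps ~ N(0, tau^2)
    y_t     = x_t + eta_t,                      eta ~ N(0, sigma^2)

    1 - b is the lag-1 autocorrelation of log abundance; r is the growth
    rate at N = 1; c the covariate effect on the standardized covariate z.
    """

    r: float = 0.101
    b: float = 0.008
    c: float = -0.067
    tau: float = 0.099
    sigma: float = 0.113
    z: np.ndarray | None = None
    x: np.ndarray | None = None
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.tau < 0 or self.sigma < 0:
            raise ValueError("tau and sigma must be >= 0")


def gen_gompertz_series(truth: GompertzTruth, n_years: int, seed: int = 0,
                        x1: float | None = None) -> GompertzTruth:
    """Simulate log abundance forward and add observation error.

    The latent series starts at the deterministic stationary point
    x* = (r + c*mean(z)) / b (or x1 if given; log 3e5 when b = 0, the scale
    of a large breeding population).  Returns a copy of `truth` with z, x, y
    filled in.
    """
    if n_years < 3:
        raise ValueError("n_years must be >= 3")
    rng = np.random.default_rng(seed)
    if truth.z is None:
        z = rng.standard_normal(n_years)
        if n_years > 1:
            z = (z - z.mean()) / z.std(ddof=0)
    else:
        z = np.asarray(truth.z, dtype=float)
        if z.size != n_years:
            raise ValueError("covariate series length must equal n_years")
    if x1 is None:
        x1 = (truth.r + truth.c * z.mean()) / truth.b if truth.b != 0 else np.log(3e5)
    x = np.empty(n_years)
    x[0] = x1
    eps = rng.normal(0.0, truth.tau, n_years - 1) if truth.tau > 0 else np.zeros(n_years - 1)
    for t in range(n_years - 1):
        x[t + 1] = x[t] + truth.r - truth.b * x[t] + truth.c * z[t] + eps[t]
    eta = rng.normal(0.0, truth.sigma, n_years) if truth.sigma > 0 else np.zeros(n_years)
    y = x + eta
    return GompertzTruth(r=truth.r, b=truth.b, c=truth.c, tau=truth.tau,
                         sigma=truth.sigma, z=z, x=x, y=y)


# ---------------------------------------------------------------------------
# colony count tables
# ---------------------------------------------------------------------------

def gen_colony_counts(n_colonies: int = 4, n_years: int = 30,
                      effects: dict | None = None,
                      missing_frac: float = 0.439, seed: int = 0,
                      overdispersion: float = 0.0) -> pd.DataFrame:
    """Multiplicative colony x year counts with cells masked at random.

    Expected count mu[i, t] = colony_effect_i * year_effect_t (a log-linear
    independence model, matching the imputation model downstream).  Counts
    are Poisson, optionally gamma-overdispersed.  Masking never removes the
    last observation of a colony or a year.  Returns a long table with
    columns colony, year, count (NaN where masked) and true_count.
    """
    if not 0 <= missing_frac < 1:
        raise ValueError("missing_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if effects is None:
        colony_eff = np.array([20000.0, 10000.0, 5000.0, 2500.0])[:n_colonies]
        if n_colonies > 4:
            colony_eff = np.concatenate(
                [colony_eff, rng.uniform(1000, 20000, n_colonies - 4)])
        year_eff = np.exp(rng.normal(0.0, 0.15, n_years))
        year_eff /= year_eff.mean()
    else:
        colony_eff = np.asarray(effects["colony"], dtype=float)
        year_eff = np.asarray(effects["year"], dtype=float)
    mu = np.outer(colony_eff, year_eff)
    if overdispersion > 0:
        shape = 1.0 / overdispersion
        mu_draw = mu * rng.gamma(shape, 1.0 / shape, size=mu.shape)
    else:
        mu_draw = mu
    counts = rng.poisson(mu_draw).astype(float)
    counts = np.maximum(counts, 1.0)  # breeding-pair counts are positive

    n_cells = n_colonies * n_years
    n_mask = int(round(missing_frac * n_cells))
    order = rng.permutation(n_cells)
    observed = np.ones(n_cells, dtype=bool)
    row_left = np.full(n_colonies, n_years)
    col_left = np.full(n_years, n_colonies)
    for idx in order:
        if n_mask == 0:
            break
        i, t = divmod(idx, n_years)
        if row_left[i] > 1 and col_left[t] > 1:
            observed[idx] = False
            row_left[i] -= 1
            col_left[t] -= 1
            n_mask -= 1
    obs = observed.reshape(n_colonies, n_years)
    rows = []
    for i in range(n_colonies):
        for t in range(n_years):
            rows.append({"colony": f"C{i + 1}", "year": 1982 + t,
                         "count": counts[i, t] if obs[i, t] else np.nan,
                         "true_count": counts[i, t]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gridded SST fields
# ---------------------------------------------------------------------------

@dataclass
class SSTTruth:
    """Planted structure of the synthetic SST fields.

    The dipole pattern has unit norm under sqrt(cos lat) weighting over the
    EOF domain and explains exactly `planted_var_frac` of the February-March
    anomaly variance there.  The 5 degC isotherm in the polar-front sector
    moves south by `pf_slope` km per degC of box SST anomaly.
    """

    planted_var_frac: float = 0.27
    pf_slope: float = 130.0  # km per degC
    dipole_amplitude: float = 3.0  # degC scale of the dipole signal
    ssta_sd: float = 0.4  # degC, interannual box-anomaly spread
    noise_sd: float = 0.05  # degC, white noise in the polar-front band
    band_lon: tuple = (48.0, 56.0)  # deg E window of the PF-coupled anomaly
    pc_series: np.ndarray | None = None
    ssta_series: np.ndarray | None = None
    dipole_pattern: xr.DataArray | None = None
    pf_lat_series: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0 < self.planted_var_frac < 1:
            raise ValueError("planted_var_frac must be in (0, 1)")


def _default_grid():
    lat = np.arange(-58.0, -9.0, 2.0)
    lon = np.arange(-50.0, 151.0, 2.0)
    return lat, lon


def _dipole_pattern(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Tilted NE-SW dipole in each basin, positive in the southwest.

    Tapered to zero south of 44 S so the subtropical mode does not leak
    into the polar-front box.
    """
    LA, LO = np.meshgrid(lat, lon, indexing="ij")
    pat = np.zeros_like(LA)
    for center in (-20.0, 80.0):  # Atlantic / Indian basin centres
        pos = np.exp(-(((LA + 38.0) / 9.0) ** 2 + ((LO - center + 12.0) / 22.0) ** 2))
        neg = np.exp(-(((LA + 22.0) / 9.0) ** 2 + ((LO - center - 12.0) / 22.0) ** 2))
        pat += pos - neg
    taper = np.clip((LA + 44.0) / 4.0, 0.0, 1.0)  # 0 at/below 44 S
    return pat * taper


def _mean_state(lat: np.ndarray, gradient: float) -> np.ndarray:
    """Meridional mean SST profile: 5 degC at 52 S, `gradient` degC/deg."""
    T = np.where(lat <= -40.0, 5.0 + gradient * (lat + 52.0),
                 5.0 + gradient * 12.0 + (24.0 - (5.0 + gradient * 12.0))
                 * (lat + 40.0) / 30.0)
    return T


def gen_sst_fields(truth: SSTTruth, n_years: int = 33, seed: int = 0,
                   grid=None, start_year: int = 1979,
                   months=(1, 2, 3)) -> tuple[xr.Dataset, SSTTruth]:
    """Monthly gridded SST with a planted dipole EOF mode and PF coupling.

    The anomaly budget over the EOF domain (10-50 S, 50 W-150 E, Feb-Mar) is
    partitioned exactly: the realized dipole signal carries
    `planted_var_frac` of the weighted sum of squares, isotropic noise
    (orthogonalized against the pattern) plus the polar-band anomaly carries
    the rest.  The 5 degC isotherm latitude responds linearly to the box
    anomaly through the meridional gradient 111.2/pf_slope degC per degree.
    """
    rng = np.random.default_rng(seed)
    lat, lon = grid if grid is not None else _default_grid()
    n_lat, n_lon = lat.size, lon.size
    months = tuple(months)
    gradient = KM_PER_DEG_LAT / truth.pf_slope  # degC per degree latitude

    base = _mean_state(lat, gradient)[:, None] * np.ones((1, n_lon))
    month_offsets = {m: off for m, off in zip(months, (0.0, 0.15, 0.30))}

    # planted dipole: unit-norm pattern under sqrt(cos lat) weights (EOF domain)
    pat = _dipole_pattern(lat, lon)
    w = np.sqrt(np.cos(np.deg2rad(lat)))[:, None] * np.ones((1, n_lon))
    dom = (lat[:, None] <= -10.0) & (lat[:, None] >= -50.0) & \
          (np.ones((n_lat, 1), dtype=bool) & ((lon >= -50.0) & (lon <= 150.0))[None, :])
    norm = np.sqrt(np.sum((pat * w)[dom] ** 2))
    pat = pat / norm

    if truth.pc_series is None:
        pc = rng.standard_normal(n_years)
    else:
        pc = np.asarray(truth.pc_series, dtype=float)
    pc = (pc - pc.mean()) / pc.std(ddof=0)  # exactly centred, unit variance

    if truth.ssta_series is None:
        ssta = rng.normal(0.0, truth.ssta_sd, n_years)
    else:
        ssta = np.asarray(truth.ssta_series, dtype=float)
    ssta = ssta - ssta.mean()
    # decorrelate from the dipole PC so the planted mode stays an exact
    # eigenvector of the anomaly covariance
    ssta = ssta - (ssta @ pc) / (pc @ pc) * pc

    # polar band anomaly: uniform over lat <= -44 (tapered out by 42 S),
    # restricted to the longitude window around the covariate box
    band = np.clip((-44.0 - lat) / 2.0 + 1.0, 0.0, 1.0)
    band[lat > -42.0] = 0.0
    lon_win = ((lon >= truth.band_lon[0]) & (lon <= truth.band_lon[1])).astype(float)
    band2d = band[:, None] * lon_win[None, :]

    # weighted sums of squares over the EOF domain, per year
    sig_amp = truth.dipole_amplitude
    sig_ss = np.sum(pc ** 2) * sig_amp ** 2  # pattern is unit-norm in domain
    band_w = (band2d * w)[dom]
    band_ss = np.sum(ssta ** 2) * np.sum(band_w ** 2)
    need_total = sig_ss / truth.planted_var_frac
    noise_ss_target = need_total - sig_ss - band_ss
    if noise_ss_target <= 0:
        raise ValueError(
            "planted_var_frac incompatible with the polar-band anomaly "
            "variance: no room left for isotropic noise")
    if band_ss >= sig_ss:
        raise ValueError(
            "polar-band variance would rival the planted dipole mode; "
            "increase dipole_amplitude or reduce ssta_sd")

    noise = rng.standard_normal((n_years, n_lat, n_lon))
    noise[:, lat < -50.0, :] = 0.0  # polar rows get only the PF noise below
    noise -= noise.mean(axis=0)  # per-cell centred over years
    # Inside the EOF domain the noise is made exactly variance-controlled:
    # orthogonal to the planted pattern and spectrally flat (equal nonzero
    # singular values), so the planted mode explains exactly
    # planted_var_frac of the domain variance by construction.
    pw = np.where(dom, pat * w, 0.0)
    pw_norm2 = np.sum(pw ** 2)
    for k in range(n_years):
        coef = np.sum(noise[k] * w * np.where(dom, pat, 0.0)) / pw_norm2
        noise[k] -= coef * pat
    # temporal orthogonality to the PC (cell time series ⟂ pc)
    flatN = noise.reshape(n_years, -1)
    flatN -= np.outer(pc, (pc @ flatN) / (pc @ pc))
    noise = flatN.reshape(n_years, n_lat, n_lon)
    dmask = dom
    Nw = (noise * w[None, :, :])[:, dmask]  # (years, domain cells), weighted
    U, s, Vt = np.linalg.svd(Nw, full_matrices=False)
    rank = int(np.sum(s > 1e-10 * s[0]))
    s_flat = np.zeros_like(s)
    s_flat[:rank] = np.sqrt(noise_ss_target / rank)
    Nw_flat = (U * s_flat) @ Vt
    w_cells = w[dmask]
    noise_scale_out = np.sqrt(noise_ss_target / (n_years * dmask.sum())) \
        / max(np.mean(w_cells), 1e-9)
    noise = noise * noise_scale_out  # comparable amplitude outside the domain
    flat_cells = Nw_flat / w_cells[None, :]
    tmp = noise.reshape(n_years, -1)
    tmp[:, dmask.ravel()] = flat_cells
    noise = tmp.reshape(n_years, n_lat, n_lon)

    anom_year = (sig_amp * pc[:, None, None] * pat[None, :, :]
                 + ssta[:, None, None] * band2d[None, :, :]
                 + noise)

    # small extra noise south of the EOF domain (keeps the isotherm
    # stochastic without entering the variance budget above)
    pf_noise = rng.normal(0.0, truth.noise_sd, (n_years, n_lat, n_lon))
    pf_mask = (lat <= -52.0)[:, None] * np.ones((1, n_lon))
    anom_year = anom_year + pf_noise * pf_mask[None, :, :]

    # seasonal cycle confined to the subtropics so it never moves the
    # polar-front isotherm (summer means south of 40 S are cycle-free)
    cyc_mask = (lat > -40.0).astype(float)[:, None] * np.ones((1, n_lon))
    times, cubes = [], []
    for k in range(n_years):
        for m in months:
            times.append(np.datetime64(f"{start_year + k}-{m:02d}-15"))
            cubes.append(base + month_offsets.get(m, 0.0) * cyc_mask
                         + anom_year[k])
    sst = xr.DataArray(np.stack(cubes), dims=("time", "lat", "lon"),
                       coords={"time": np.array(times), "lat": lat, "lon": lon},
                       name="sst", attrs={"units": "degC"})
    ds = sst.to_dataset()

    pf_lat = -52.0 - ssta / gradient  # southward (more negative) when warm
    out = SSTTruth(planted_var_frac=truth.planted_var_frac,
                   pf_slope=truth.pf_slope,
                   dipole_amplitude=truth.dipole_amplitude,
                   ssta_sd=truth.ssta_sd, noise_sd=truth.noise_sd,
                   pc_series=pc, ssta_series=ssta,
                   dipole_pattern=xr.DataArray(pat, dims=("lat", "lon"),
                                               coords={"lat": lat, "lon": lon}),
                   pf_lat_series=pf_lat)
    return ds, out


# ---------------------------------------------------------------------------
# bout-level covariate tables
# ---------------------------------------------------------------------------

BOUT_COVARIATES = ["log_n_dives", "log_n_dives_sq", "max_depth", "n_wiggles",
                   "ascent_rate", "descent_rate", "n_steps", "surface_duration"]

#: standardized-scale coefficients used as default simulation truth
#: (intercept, then BOUT_COVARIATES order)
DEFAULT_BOUT_BETA = {
    "intercept": 3.13, "log_n_dives": 1.45, "log_n_dives_sq": -0.25,
    "max_depth": 0.0, "n_wiggles": 0.32, "ascent_rate": 0.0,
    "descent_rate": 0.47, "n_steps": 0.0, "surface_duration": -0.25,
}


def gen_bout_table(beta: dict | None = None, theta: float = 12.0,
                   n_bouts: int = 36 + 38, seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Bout-level covariates and negative-binomial feeding-event counts.

    Covariates are drawn on natural scales, then the standardized versions
    (columns suffixed ``_std``) enter the linear predictor with the truth
    coefficients `beta`; counts ~ NB(mean = exp(eta), dispersion `theta`)
    with Var = mu + mu^2/theta.  Default n_bouts = 74 (36 fit + 38 validation).
    """
    if theta <= 0:
        raise ValueError("NB dispersion theta must be > 0")
    beta = dict(DEFAULT_BOUT_BETA if beta is None else beta)
    rng = np.random.default_rng(seed)
    n_dives = rng.integers(3, 60, n_bouts).astype(float)
    log_nd = np.log(n_dives)
    raw = pd.DataFrame({
        "log_n_dives": log_nd,
        # squared on the centred scale: keeps curvature identifiable
        # instead of collinear with the linear term
        "log_n_dives_sq": (log_nd - log_nd.mean()) ** 2,
        "max_depth": rng.uniform(50.0, 306.0, n_bouts),
        "n_wiggles": rng.poisson(3.0, n_bouts).astype(float),
        "ascent_rate": rng.normal(1.3, 0.15, n_bouts),
        "descent_rate": rng.normal(1.3, 0.15, n_bouts),
        "n_steps": rng.poisson(1.0, n_bouts).astype(float),
        "surface_duration": rng.uniform(60.0, 400.0, n_bouts),
    })
    std = (raw - raw.mean()) / raw.std(ddof=0)
    eta = np.full(n_bouts, float(beta.get("intercept", 0.0)))
    for name in BOUT_COVARIATES:
        eta += float(beta.get(name, 0.0)) * std[name].to_numpy()
    mu = np.exp(eta)
    lam = rng.gamma(theta, mu / theta)  # NB as gamma-Poisson mixture
    counts = rng.poisson(lam)
    table = raw.copy()
    for name in BOUT_COVARIATES:
        table[name + "_std"] = std[name]
    table.insert(0, "feeding_events", counts)
    truth = {"beta": beta, "theta": theta, "mu": mu}
    return table, truth
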