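"""Extract dives, wiggles, steps, bouts, feeding events and thermocline
depth from biologging time series.

Definitions follow the field conventions for time-depth-recorder data:

* a **wiggle** is a brief depth reversal — the vertical speed passes below
  0 m/s over three successive samples and then resumes — counted within the
  descent and bottom phases (ascent excluded, where upward motion is the
  prevailing direction);
* a **step** is a maximal period within descent or ascent where the
  vertical speed falls to at most 0.35 m/s without reversing sign;
* a **feeding event** is an oesophageal temperature drop whose maximum
  descending rate reaches 0.06 degC/s (with amplitude/duration gates);
* the **thermocline** is the depth of the maximum vertical temperature
  gradient.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .records import (DepthRecord, TemperatureRecord, Dive, FeedingEvent,
                      DiveBout, ThermoclineEstimate)

#: feeding-event rate threshold, degC/s
RATE_THRESHOLD = 0.06
#: step speed threshold, m/s
STEP_SPEED = 0.35
#: fraction of max depth defining the bottom phase
BOTTOM_FRAC = 0.8


def vertical_speed(rec: DepthRecord) -> np.ndarray:
    """Forward-difference vertical speed (m/s, positive descending).

    Length n-1: element i is the speed over [t_i, t_{i+1}].
    """
    return np.diff(rec.depth) / np.diff(rec.time)


def detect_dives(rec: DepthRecord, min_depth: float = 3.0,
                 surface_threshold: float = 0.5) -> list[Dive]:
    """Maximal submerged intervals reaching at least `min_depth` metres.

    Submerged means depth > `surface_threshold`.  Phases: the bottom phase
    is where depth >= 80% of the dive's maximum; descent runs from the
    start to the first bottom entry, ascent from the last bottom exit to
    the end.  Descent/ascent rates are the phase depth span over the phase
    duration.
    """
    if min_depth <= 0:
        raise ValueError("min_depth must be positive")
    if rec.depth.size == 0:
        return []
    sub = rec.depth > surface_threshold
    edges = np.flatnonzero(np.diff(sub.astype(int)))
    starts = list(edges[~sub[edges]] )
    ends = list(edges[sub[edges]] + 1)
    if sub[0]:
        starts.insert(0, 0)
    if sub[-1]:
        ends.append(rec.depth.size - 1)
    dives: list[Dive] = []
    raw = []
    for s, e in zip(starts, ends):
        seg = rec.depth[s:e + 1]
        dmax = float(seg.max())
        if dmax < min_depth:
            continue
        bottom = np.flatnonzero(seg >= BOTTOM_FRAC * dmax)
        bs, be = s + int(bottom[0]), s + int(bottom[-1])
        t = rec.time
        desc_dur = t[bs] - t[s]
        asc_dur = t[e] - t[be]
        desc_rate = (rec.depth[bs] - rec.depth[s]) / desc_dur if desc_dur > 0 else np.nan
        asc_rate = (rec.depth[be] - rec.depth[e]) / asc_dur if asc_dur > 0 else np.nan
        raw.append((s, e, bs, be, dmax, desc_rate, asc_rate))
    for k, (s, e, bs, be, dmax, dr, ar) in enumerate(raw):
        post = np.nan
        if k + 1 < len(raw):
            post = rec.time[raw[k + 1][0]] - rec.time[e]
        dives.append(Dive(start=s, end=e, bottom_start=bs, bottom_end=be,
                          max_depth=dmax, duration=float(rec.time[e] - rec.time[s]),
                          descent_rate=float(dr), ascent_rate=float(ar),
                          post_dive_surface=float(post)))
    return dives


def count_wiggles(dive: Dive, rec: DepthRecord) -> int:
    """Number of depth reversals within the descent + bottom phases.

    A wiggle is a maximal run of negative vertical speed (depth decreasing,
    i.e. moving toward the surface) bounded by non-negative speed on both
    sides — one wiggle per below-zero excursion of the speed trace.
    """
    v = vertical_speed(rec)
    # speeds indexed by their left sample; descent+bottom covers
    # [start, bottom_end): the prevailing direction there is downward/flat
    lo, hi = dive.start, dive.bottom_end
    seg = v[lo:hi]
    if seg.size == 0:
        return 0
    neg = seg < 0
    # maximal negative runs; a run must return to >= 0 inside the segment
    # (a run touching the right edge merges into the ascent, not a wiggle)
    padded = np.concatenate(([0], neg.astype(int), [1]))
    starts = np.flatnonzero(np.diff(padded) == 1)
    ends = np.flatnonzero(np.diff(padded) == -1)
    return int(np.sum(ends < seg.size))


def count_steps(dive: Dive, rec: DepthRecord,
                speed_threshold: float = STEP_SPEED) -> int:
    """Maximal within-phase periods where |speed| falls to <= threshold.

    Counted separately in the descent and ascent phases; the speed must not
    reverse against the phase direction inside a step (a reversal is a
    wiggle, not a step).
    """
    if speed_threshold <= 0:
        raise ValueError("speed_threshold must be positive")
    v = vertical_speed(rec)
    n = 0
    # descent: speeds in [0, thr] (downward or flat, slow)
    seg = v[dive.start:dive.bottom_start]
    slow = (seg >= 0) & (seg <= speed_threshold)
    n += int(np.flatnonzero(np.diff(np.concatenate(([0], slow.astype(int)))) == 1).size)
    # ascent: speeds in [-thr, 0] (upward or flat, slow)
    seg = v[dive.bottom_end:dive.end]
    slow = (seg <= 0) & (seg >= -speed_threshold)
    n += int(np.flatnonzero(np.diff(np.concatenate(([0], slow.astype(int)))) == 1).size)
    return n


def detect_feeding_events(rec: TemperatureRecord,
                          rate_threshold: float = RATE_THRESHOLD,
                          min_amplitude: float = 0.1,
                          max_duration: float = 300.0,
                          recovery_frac: float = 0.5) -> list[FeedingEvent]:
    """Qualifying oesophageal temperature drops.

    The trace is segmented into candidate drop episodes: maximal runs of
    declining temperature, merged with a following decline when the rebound
    between them recovers less than `recovery_frac` of the drop amplitude.
    An episode qualifies when its maximum descending rate (adjacent-sample
    finite difference) >= `rate_threshold`, its peak-to-trough amplitude
    >= `min_amplitude` and its duration <= `max_duration`.

    Raising `rate_threshold` never increases the event count (episode
    construction does not depend on it).
    """
    t, T = rec.time, rec.temperature
    if t.size < 2:
        return []
    dts = np.diff(t)
    if not np.allclose(dts, dts[0], rtol=1e-6):
        gap = int(np.argmax(np.abs(dts - dts[0])))
        raise ValueError(
            f"non-uniform sampling: step of {dts[gap]:.3f}s at t={t[gap]:.1f}s "
            f"(expected {dts[0]:.3f}s)")
    dT = np.diff(T)
    declining = dT < 0
    # maximal declining runs -> (i_peak, i_trough) index pairs
    runs = []
    i = 0
    n = declining.size
    while i < n:
        if declining[i]:
            j = i
            while j + 1 < n and declining[j + 1]:
                j += 1
            runs.append((i, j + 1))  # samples i..j+1, peak at i, trough at j+1
            i = j + 1
        else:
            i += 1
    # merge runs separated by insufficient recovery
    episodes = []
    for pk, tr in runs:
        if episodes:
            ppk, ptr = episodes[-1]
            amp_prev = T[ppk] - T[ptr]
            rebound = T[pk] - T[ptr]
            if amp_prev > 0 and rebound < recovery_frac * amp_prev:
                episodes[-1] = (ppk, tr if T[tr] < T[ptr] else ptr)
                continue
        episodes.append((pk, tr))
    events = []
    for pk, tr in episodes:
        amp = float(T[pk] - T[tr])
        dur = float(t[tr] - t[pk])
        max_rate = float(np.max(-dT[pk:tr] / dts[pk:tr]))
        if max_rate >= rate_threshold and amp >= min_amplitude and dur <= max_duration:
            events.append(FeedingEvent(onset=float(t[pk]), drop_rate=max_rate,
                                       amplitude=amp, duration=dur))
    return events


def segment_bouts(dives: list[Dive], gap_threshold: float = 1800.0,
                  rec: DepthRecord | None = None,
                  wiggles: list[int] | None = None,
                  steps: list[int] | None = None) -> list[DiveBout]:
    """Group time-ordered dives into bouts by post-dive surface interval.

    Consecutive dives whose separating surface interval is below
    `gap_threshold` share a bout.  Bout covariates are the per-dive means
    of the standard bout-table columns (max depth, wiggles, steps, ascent
    and descent rates, surface duration), plus log(n dives) and its square.
    """
    if not dives:
        return []
    groups = [[0]]
    for k in range(1, len(dives)):
        gap = dives[k - 1].post_dive_surface
        if np.isnan(gap) or gap >= gap_threshold:
            groups.append([k])
        else:
            groups[-1].append(k)
    bouts = []
    for g in groups:
        members = [dives[k] for k in g]
        nd = len(g)
        cov = {
            "log_n_dives": float(np.log(nd)),
            "log_n_dives_sq": float(np.log(nd) ** 2),
            "max_depth": float(np.mean([d.max_depth for d in members])),
            "ascent_rate": float(np.nanmean([d.ascent_rate for d in members])),
            "descent_rate": float(np.nanmean([d.descent_rate for d in members])),
            "surface_duration": float(np.nanmean(
                [d.post_dive_surface for d in members])),
        }
        if rec is not None:
            cov["n_wiggles"] = float(np.mean([count_wiggles(d, rec) for d in members]))
            cov["n_steps"] = float(np.mean([count_steps(d, rec) for d in members]))
        elif wiggles is not None:
            cov["n_wiggles"] = float(np.mean([wiggles[k] for k in g]))
            cov["n_steps"] = float(np.mean([steps[k] for k in g]))
        bouts.append(DiveBout(dive_indices=list(g), n_dives=nd, covariates=cov))
    return bouts


def estimate_thermocline(profiles, bin_width: float = 2.0,
                         smooth_bins: int = 5) -> ThermoclineEstimate | None:
    """Depth of the maximum vertical temperature gradient.

    Parameters
    ----------
    profiles : sequence of (depth, temperature) array pairs
        One pair per dive; binned to a regular `bin_width`-metre grid and
        combined by the median across dives before differentiation.

    Returns None (with a warning) when the combined profile is shallower
    than 50 m or has no gradient maximum (isothermal water).  Ties in the
    gradient maximum (a plateau) resolve to the plateau midpoint.
    """
    depths = np.concatenate([np.asarray(d, dtype=float) for d, _ in profiles])
    temps = np.concatenate([np.asarray(T, dtype=float) for _, T in profiles])
    if depths.size < 5 or depths.max() - depths.min() < 100.0:
        raise ValueError("need >= 5 depth levels spanning >= 100 m")
    if depths.max() < 50.0:
        warnings.warn("profile shallower than 50 m; no thermocline estimate")
        return None
    grid = np.arange(np.floor(depths.min() / bin_width) * bin_width,
                     depths.max() + bin_width, bin_width)
    idx = np.digitize(depths, grid)
    prof = np.full(grid.size, np.nan)
    for k in range(grid.size):
        sel = idx == k + 1
        if np.any(sel):
            prof[k] = np.median(temps[sel])
    valid = ~np.isnan(prof)
    g, p = grid[valid] + bin_width / 2.0, prof[valid]
    if g.size < 5:
        raise ValueError("too few populated depth bins")
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        pad = smooth_bins // 2
        p = np.convolve(np.pad(p, pad, mode="edge"), kernel, mode="valid")
    grad = np.gradient(p, g)
    mag = np.abs(grad)
    if mag.max() < 1e-9:
        warnings.warn("isothermal profile; no thermocline")
        return None
    top = np.flatnonzero(mag >= mag.max() - 1e-9)  # plateau of maximal gradient
    mid = int(round(float(np.mean([top[0], top[-1]]))))
    return ThermoclineEstimate(depth=float(g[mid]), gradient=float(grad[mid]))


def phase_feeding_comparison(transit, polar_front):
    """Mann-Whitney rank-sum comparison of per-unit feeding rates.

    Exact two-sided p for small samples (n <= 12 per group, no ties),
    normal approximation with tie correction otherwise.  Returns (U, p)
    with U the statistic for the first sample.
    """
    a = np.asarray(transit, dtype=float)
    b = np.asarray(polar_front, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.all(a == b[0]) and np.all(b == b[0]):
        return 0.5 * a.size * b.size, 1.0
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 12 and b.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
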