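"""Synthetic central-place foraging world with known ground truth.

Emulates a seabird colony on a coast: birds make round trips over a
shelf sea, performing prolonged U-shaped dives (descent, bottom phase,
ascent) in shallow, flat, cool-water habitat and brief V-shaped plunge
dives over a broader, warmer, steeper-sloped habitat.  GPS fixes are
logged every ``fix_interval`` seconds and depth at 1 Hz during
submersion.  Every dive carries a truth label and a truth suitability
surface exists per dive shape, so the downstream detection, contingency,
kernel-density and habitat-model stages can all be tested for parameter
recovery without any real tracking data.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import EnvStack, Grid, haversine_km, slope_degrees

__all__ = ["SimConfig", "SimTruth", "gen_environment", "gen_tracks_and_dives", "default_u_fraction"]

SECONDS_PER_DAY = 86400


def default_u_fraction(drop_day: int = 26, before: float = 0.45, after: float = 0.05) -> Callable[[int], float]:
    """Daily U-dive probability with a marked mid-season drop.

    Mirrors the phenology in which deep dives for cold-water prey fall out
    of favour part-way through chick-rearing: ``before`` until day-of-study
    ``drop_day`` (0-based), ``after`` from then on.
    """

    def u_fraction(day: int) -> float:
        return before if day < drop_day else after

    return u_fraction


@dataclass
class SimConfig:
    """Stated world for the simulator.  Defaults describe a Newfoundland-like
    shelf system: a coastal colony, mid-July to mid-September season,
    15-min GPS fixes and 1-s depth sampling."""

    colony: tuple[float, float] = (-54.18, 46.81)  # lon, lat
    n_birds: int = 8
    date_range: tuple[dt.date, dt.date] = (dt.date(2021, 7, 15), dt.date(2021, 9, 9))
    fix_interval: int = 900  # s
    dive_rate: float = 8.0  # mean dives per trip
    u_fraction_by_day: Callable[[int], float] | dict[int, float] | None = None
    # per-shape suitability weights on standardised (bathy, slope, sst)
    habitat_truth: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "U": {"bathy": -1.8, "slope": -1.0, "sst": -1.2},
            "V": {"bathy": -0.4, "slope": 0.8, "sst": 0.8},
        }
    )
    # SST field: mean at season start, °C/day warming, °C per degree
    # latitude (southward), spatial noise sd
    sst_mean: float = 12.0
    sst_warming_per_day: float = 0.08
    sst_lat_gradient: float = 0.8
    sst_noise_sd: float = 0.4
    # grid: (lon_min, lat_min, lon_max, lat_max), cell in degrees
    extent: tuple[float, float, float, float] = (-58.0, 44.0, -51.0, 48.5)
    cell: float = 0.05
    coast_lat: float = 46.9  # land north of this latitude
    max_range_km: float = 250.0  # central-place constraint on dive sites
    flight_speed_kmh: float = 55.0
    depth_noise_sd: float = 0.1  # m, pressure-sensor noise
    # shape-parameter margins away from the classifier boundaries
    u_depth: tuple[float, float] = (12.0, 25.0)
    u_bottom: tuple[float, float] = (5.0, 15.0)
    v_depth: tuple[float, float] = (1.5, 7.5)
    v_duration: tuple[int, int] = (4, 8)
    seed: int = 0

    def __post_init__(self):
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        if self.date_range[1] < self.date_range[0]:
            raise ValueError("date_range is empty")
        if self.u_fraction_by_day is None:
            self.u_fraction_by_day = default_u_fraction()

    def u_fraction(self, day: int) -> float:
        f = self.u_fraction_by_day
        p = f[day] if isinstance(f, dict) else f(day)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"u_fraction for day {day} outside [0, 1]: {p}")
        return p

    @property
    def days(self) -> list[dt.date]:
        start, end = self.date_range
        return [start + dt.timedelta(days=i) for i in range((end - start).days + 1)]


@dataclass
class SimTruth:
    """Ground truth emitted alongside the synthetic data."""

    dives: pd.DataFrame  # bird_id, timestamp, lon, lat, shape, day
    suitability: dict[str, Grid]  # per-shape truth surface in [0, 1]
    linear_predictor: dict[str, Grid]  # per-shape sampling log-weights
    weights: dict[str, dict[str, float]]  # generating covariate weights
    cutoff_day: int | None = None


def _smooth_noise(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    """Unit-variance spatially smooth Gaussian field."""
    z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_cells, mode="reflect")
    return z / max(z.std(), 1e-12)


def gen_environment(config: SimConfig) -> EnvStack:
    """Build bathymetry, slope, land/sea mask and a daily SST stack.

    Bathymetry deepens away from the coast with smooth mesoscale relief;
    slope is derived from it by finite differences.  SST has a meridional
    gradient (warmer south), warms linearly through the season and carries
    smooth spatial noise, so an early/late temperature contrast exists.
    """
    lon_min, lat_min, lon_max, lat_max = config.extent
    ncol = int(round((lon_max - lon_min) / config.cell))
    nrow = int(round((lat_max - lat_min) / config.cell))
    if nrow < 2 or ncol < 2:
        raise ValueError("degenerate grid: need at least 2x2 cells")
    lon_c, lat_c = config.colony
    if not (lon_min < lon_c < lon_max and lat_min < lat_c < lat_max):
        raise ValueError("grid extent must contain the colony")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    proto = Grid(lon_min, lat_min, config.cell, np.zeros((nrow, ncol)))
    lon2d, lat2d = proto.cell_centres()

    sea = lat2d < config.coast_lat
    # depth: ramp away from the coastline + smooth relief, floored at 5 m
    dist_coast_deg = np.maximum(config.coast_lat - lat2d, 0.0)
    relief = 60.0 * _smooth_noise(rng, (nrow, ncol), 6.0)
    depth = 25.0 + 140.0 * dist_coast_deg + relief
    depth = np.maximum(depth, 5.0)
    depth[~sea] = np.nan

    bathy = proto.like(depth)
    slope = slope_degrees(proto.like(np.where(sea, depth, 0.0)))
    slope.data[~sea] = np.nan

    sst_pattern = _smooth_noise(rng, (nrow, ncol), 8.0)
    sst = {}
    for day, date in enumerate(config.days):
        field_ = (
            config.sst_mean
            + config.sst_warming_per_day * day
            + config.sst_lat_gradient * (config.coast_lat - lat2d)
            + config.sst_noise_sd * sst_pattern
        )
        field_ = field_.copy()
        field_[~sea] = np.nan
        sst[date] = proto.like(field_)

    return EnvStack(bathy=bathy, slope=slope, sea=proto.like(sea.astype(float)), sst=sst)


def _standardise(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    v = values[mask]
    return (values - v.mean()) / max(v.std(), 1e-12)


def _truth_fields(config: SimConfig, env: EnvStack) -> tuple[dict[str, Grid], dict[str, Grid], np.ndarray]:
    """Per-shape linear predictor and [0,1] suitability on reachable sea cells."""
    sea = env.sea_mask()
    lon2d, lat2d = env.grid.cell_centres()
    reach = sea & (haversine_km(config.colony[0], config.colony[1], lon2d, lat2d) <= config.max_range_km)
    if not reach.any():
        raise ValueError("no sea cells within foraging range of the colony")
    sst_mean = np.mean([g.data for g in env.sst.values()], axis=0)
    covs = {
        "bathy": _standardise(np.nan_to_num(env.bathy.data), reach),
        "slope": _standardise(np.nan_to_num(env.slope.data), reach),
        "sst": _standardise(np.nan_to_num(sst_mean), reach),
    }
    lp, suit = {}, {}
    for shape, weights in config.habitat_truth.items():
        missing = set(weights) - set(covs)
        if missing:
            raise KeyError(f"habitat_truth references missing layer(s): {sorted(missing)}")
        eta = np.zeros_like(covs["bathy"])
        for name, w in weights.items():
            eta += w * covs[name]
        eta[~reach] = -np.inf
        lp[shape] = env.grid.like(eta)
        s = 1.0 / (1.0 + np.exp(-eta))
        s[~reach] = 0.0
        suit[shape] = env.grid.like(s)
    return lp, suit, reach


def _dive_sites(rng, lp: Grid, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw n dive cells with probability ∝ exp(linear predictor); jitter
    uniformly within the cell."""
    eta = lp.data
    finite = np.isfinite(eta)
    w = np.zeros_like(eta)
    w[finite] = np.exp(eta[finite] - eta[finite].max())
    p = (w / w.sum()).ravel()
    flat = rng.choice(p.size, size=n, p=p)
    i, j = np.unravel_index(flat, eta.shape)
    lon = lp.lon0 + (j + rng.uniform(0, 1, n)) * lp.cell
    lat = lp.lat0 + (i + rng.uniform(0, 1, n)) * lp.cell
    return lon, lat


def _u_profile(rng, config: SimConfig) -> np.ndarray:
    """U dive: descend, flat bottom phase, ascend (1 Hz samples)."""
    depth = rng.uniform(*config.u_depth)
    bottom_s = int(rng.integers(config.u_bottom[0], config.u_bottom[1] + 1))
    rate = rng.uniform(1.2, 1.8)  # m/s vertical speed
    n_leg = max(int(np.ceil(depth / rate)), 2)
    down = depth * np.arange(1, n_leg) / n_leg
    bottom = np.full(bottom_s, depth) * rng.uniform(0.99, 1.0, bottom_s)
    return np.concatenate([down, bottom, down[::-1]])

def _v_profile(rng, config: SimConfig) -> np.ndarray:
    """V dive: brief triangular spike, no bottom phase."""
    depth = rng.uniform(*config.v_depth)
    n = int(rng.integers(config.v_duration[0], config.v_duration[1] + 1))
    half = (n + 1) // 2
    down = depth * np.arange(1, half + 1) / half
    up = down[:-1][::-1] * rng.uniform(0.55, 0.75)
    return np.concatenate([down, up])[:n]


def _order_sites(lon, lat, colony):
    """Greedy nearest-neighbour tour from the colony over the dive sites."""
    order, left = [], list(range(len(lon)))
    cur = colony
    while left:
        d = haversine_km(cur[0], cur[1], lon[left], lat[left])
        k = left[int(np.argmin(d))]
        order.append(k)
        left.remove(k)
        cur = (lon[k], lat[k])
    return order


def gen_tracks_and_dives(config: SimConfig, env: EnvStack):
    """Simulate trips, GPS fixes and 1-Hz depth traces.

    Returns ``(fixes, traces, truth)``: fixes as a DataFrame
    (bird_id, timestamp, lon, lat, trip_id), traces as a DataFrame
    (bird_id, timestamp, depth_m), and the :class:`SimTruth`.

    Each bird makes one round trip per day along a greedy tour of its dive
    sites, which are drawn per shape with probability proportional to
    ``exp(linear predictor)`` of the truth weights (U/V split by the daily
    ``u_fraction``).  Fixes are logged every ``fix_interval`` seconds along
    the trajectory, plus one fix at the dive site shortly before each dive
    so that every dive has a qualifying foraging location.  Fully
    reproducible from ``config.seed``.
    """
    lp, suit, _ = _truth_fields(config, env)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    start_date = config.date_range[0]
    speed_kms = config.flight_speed_kmh / 3600.0

    fix_rows, trace_rows, truth_rows = [], [], []
    drop_day = None
    if callable(config.u_fraction_by_day):
        fracs = [config.u_fraction(d) for d in range(len(config.days))]
        drops = np.diff(fracs)
        if len(drops) and drops.min() < -0.2:
            drop_day = int(np.argmin(drops)) + 1

    for b in range(config.n_birds):
        bird = f"bird{b:02d}"
        t_next = 0.0  # per-bird clock: a trip never starts before the last ended
        for day, date in enumerate(config.days):
            n_dives = rng.poisson(config.dive_rate)
            if n_dives == 0:
                continue
            p_u = config.u_fraction(day)
            shapes = np.where(rng.uniform(size=n_dives) < p_u, "U", "V")
            lon = np.empty(n_dives)
            lat = np.empty(n_dives)
            for shape in ("U", "V"):
                sel = shapes == shape
                if sel.any():
                    lon[sel], lat[sel] = _dive_sites(rng, lp[shape], int(sel.sum()))
            order = _order_sites(lon, lat, config.colony)
            lon, lat, shapes = lon[order], lat[order], shapes[order]

            # piecewise-linear tour: colony -> sites -> colony
            px = np.concatenate([[config.colony[0]], lon, [config.colony[0]]])
            py = np.concatenate([[config.colony[1]], lat, [config.colony[1]]])
            leg_km = haversine_km(px[:-1], py[:-1], px[1:], py[1:])
            leg_s = np.maximum(leg_km / speed_kms, 1.0)
            arrive = np.cumsum(leg_s)  # arrival time at each site (and home)
            t0 = max(day * SECONDS_PER_DAY + 6 * 3600 + float(rng.integers(0, 1800)), t_next)

            # regular fixes along the trajectory
            total_s = arrive[-1]
            n_fix = int(total_s // config.fix_interval) + 1
            for k in range(n_fix):
                ts = k * config.fix_interval
                leg = np.searchsorted(arrive, ts)
                if leg >= len(leg_s):
                    break
                t_in = ts - (arrive[leg - 1] if leg else 0.0)
                f = t_in / leg_s[leg]
                fix_rows.append((bird, t0 + ts, px[leg] + f * (px[leg + 1] - px[leg]),
                                 py[leg] + f * (py[leg + 1] - py[leg]), day))
            fix_rows.append((bird, t0 + total_s, config.colony[0], config.colony[1], day))

            # dives at site arrival times, with a pre-dive fix at the site;
            # a running clock keeps successive dives >= 120 s apart so
            # traces of distinct dives never interleave
            t_cursor = t0
            for k in range(n_dives):
                t_dive = max(t0 + arrive[k] + float(rng.integers(60, 600)), t_cursor + 120.0)
                t_fix = t_dive - float(rng.integers(60, 900))
                fix_rows.append((bird, t_fix, lon[k], lat[k], day))
                profile = _u_profile(rng, config) if shapes[k] == "U" else _v_profile(rng, config)
                profile = profile + rng.normal(0.0, config.depth_noise_sd, profile.size)
                profile = np.maximum(profile, 0.02)
                times = t_dive + np.arange(profile.size + 2)
                depths = np.concatenate([[0.0], profile, [0.0]])
                trace_rows.extend(zip([bird] * times.size, times, depths))
                truth_rows.append((bird, t_dive + 1.0, lon[k], lat[k], shapes[k], day))
                t_cursor = times[-1]
            t_next = max(t0 + total_s, t_cursor) + 1800.0

    def _stamp(col):
        base = pd.Timestamp(start_date, tz="UTC")
        return base + pd.to_timedelta(np.round(col).astype(np.int64), unit="s")

    fixes = pd.DataFrame(fix_rows, columns=["bird_id", "t", "lon", "lat", "day"])
    fixes["trip_id"] = fixes["bird_id"] + "-d" + fixes["day"].astype(str)
    fixes["timestamp"] = _stamp(fixes.pop("t"))
    fixes = (fixes[["bird_id", "timestamp", "lon", "lat", "trip_id"]]
             .sort_values(["bird_id", "timestamp"], kind="stable")
             .drop_duplicates(["bird_id", "timestamp"])
             .reset_index(drop=True))

    traces = pd.DataFrame(trace_rows, columns=["bird_id", "t", "depth_m"])
    traces["timestamp"] = _stamp(traces["t"])
    traces = (traces.sort_values(["bird_id", "t"], kind="stable")
              .drop_duplicates(["bird_id", "timestamp"])
              [["bird_id", "timestamp", "depth_m"]]
              .reset_index(drop=True))

    dives = pd.DataFrame(truth_rows, columns=["bird_id", "t", "lon", "lat", "shape", "day"])
    dives["timestamp"] = _stamp(dives.pop("t"))
    dives = dives[["bird_id", "timestamp", "lon", "lat", "shape", "day"]]

    truth = SimTruth(dives=dives, suitability=suit, linear_predictor=lp,
                     weights={k: dict(v) for k, v in config.habitat_truth.items()},
                     cutoff_day=drop_day)
    return fixes, traces, truth
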