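"""Presence / pseudo-absence habitat-suitability modelling.

For each dive type, foraging GPS locations are presences (label 1) and
3x as many background points drawn uniformly over the analysis domain
(sea cells within 1.1x the maximum colony-to-dive great-circle
distance) are pseudo-absences (label 0), each assigned a uniform random
date within that year's tracking period.  Environmental covariates
(depth, slope, daily SST, lon/lat) are extracted per point, smooth terms
are screened for pairwise concurvity (> 0.9 drops the offender,
distance-to-colony first), a binomial GAM is fitted, and all subsets of
the smooth terms are compared by AICc (year always retained).  The
selected model predicts a daily habitat-suitability index (HSI) over the
domain, summarised as pixel-wise mean and standard deviation maps.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .gam import BinomialGam, GamFit, SmoothTerm, TensorTerm
from .grids import EnvStack, Grid, haversine_km

__all__ = [
    "Domain", "HSIMaps", "SelectionResult",
    "build_domain", "sample_pseudo_absences", "extract_covariates",
    "concurvity_screen", "pairwise_concurvity", "fit_gam", "select_model",
    "predict_daily", "summarize_hsi",
]

log = logging.getLogger("divehab.habitat")

DEFAULT_SMOOTHS = ("bathy", "slope", "sst")
SPATIAL_TERM = ("lon", "lat")


@dataclass
class Domain:
    """Analysis domain: sea cells within the scaled foraging radius."""

    mask: Grid  # 1 = in domain
    radius_km: float
    colony: tuple[float, float]
    year_ranges: dict[int, tuple[dt.date, dt.date]] = field(default_factory=dict)

    def cells(self) -> np.ndarray:
        return self.mask.data.astype(bool)

    @property
    def n_cells(self) -> int:
        return int(self.cells().sum())


@dataclass
class HSIMaps:
    """Daily HSI stack with mean and SD summaries (values in [0, 1])."""

    dates: list[dt.date]
    daily: np.ndarray  # (n_dates, nrow, ncol); NaN outside the domain
    mean: Grid
    sd: Grid


@dataclass
class SelectionResult:
    best: GamFit
    table: pd.DataFrame  # one row per candidate subset, sorted by AICc
    fits: dict[frozenset, GamFit]


def build_domain(colony, dive_locations: pd.DataFrame, env: EnvStack,
                 scale: float = 1.1, year_ranges=None) -> Domain:
    """Sea cells within ``scale x`` the maximum colony-to-dive distance.

    The radius rule generalises the hand-drawn east/west construction of
    typical foraging-domain maps; the conventional 1.1 scale is kept.
    """
    if dive_locations.empty:
        raise ValueError("need at least one dive location")
    d = haversine_km(colony[0], colony[1],
                     dive_locations["lon"].to_numpy(), dive_locations["lat"].to_numpy())
    radius = float(scale * np.nanmax(d))
    lon2d, lat2d = env.grid.cell_centres()
    inside = (haversine_km(colony[0], colony[1], lon2d, lat2d) <= max(radius, env.grid.cell * 111.2)) \
        & env.sea_mask()
    if not inside.any():
        raise ValueError("empty domain: no sea cells within the foraging radius")
    if year_ranges is None:
        time_col = next((c for c in ("timestamp", "start_time", "date") if c in dive_locations), None)
        dates = pd.to_datetime(dive_locations[time_col]).dt.date if time_col else None
        year_ranges = {}
        if dates is not None:
            for year, g in pd.DataFrame({"d": dates}).groupby(pd.Index(dates).map(lambda x: x.year)):
                year_ranges[int(year)] = (g["d"].min(), g["d"].max())
    return Domain(env.grid.like(inside.astype(float)), radius, tuple(colony), year_ranges)


def sample_pseudo_absences(presences: pd.DataFrame, domain: Domain,
                           ratio: int = 3, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Exactly ``ratio`` background points per presence, uniform over domain
    sea cells (uniform within the cell), each with a uniform random date in
    its year's tracking period.  Reproducible from ``seed``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = ratio * len(presences)
    if n == 0:
        return pd.DataFrame(columns=["lon", "lat", "date", "year", "label"])
    cells = np.flatnonzero(domain.cells().ravel())
    if cells.size == 0:
        raise ValueError("domain has no cells")
    grid = domain.mask
    years = pd.to_datetime(presences["date"]).dt.year if "date" in presences else presences["year"]
    counts = pd.Series(years).value_counts().sort_index()
    rows = []
    for year, n_pres in counts.items():
        year = int(year)
        m = ratio * int(n_pres)
        flat = rng.choice(cells, size=m)
        i, j = np.unravel_index(flat, grid.shape)
        lon = grid.lon0 + (j + rng.uniform(0, 1, m)) * grid.cell
        lat = grid.lat0 + (i + rng.uniform(0, 1, m)) * grid.cell
        start, end = domain.year_ranges[year]
        span = (end - start).days
        dates = [start + dt.timedelta(days=int(k)) for k in rng.integers(0, span + 1, m)]
        rows.append(pd.DataFrame({"lon": lon, "lat": lat, "date": dates,
                                  "year": year, "label": 0}))
    return pd.concat(rows, ignore_index=True)


def extract_covariates(records: pd.DataFrame, env: EnvStack,
                       colony=None) -> pd.DataFrame:
    """Attach bathy, slope and date-matched SST (and optionally
    distance-to-colony) to each point; points on land/no-data cells are
    dropped with a logged count."""
    out = records.copy().reset_index(drop=True)
    lon = out["lon"].to_numpy(dtype=float)
    lat = out["lat"].to_numpy(dtype=float)
    out["bathy"] = env.bathy.value_at(lon, lat)
    out["slope"] = env.slope.value_at(lon, lat)
    sst = np.full(len(out), np.nan)
    for date, idx in out.groupby(pd.to_datetime(out["date"]).dt.date).groups.items():
        layer = env.sst_on(date)
        sst[np.asarray(idx)] = layer.value_at(lon[np.asarray(idx)], lat[np.asarray(idx)])
    out["sst"] = sst
    if colony is not None:
        out["dist_colony"] = haversine_km(colony[0], colony[1], lon, lat)
    ok = out[["bathy", "slope", "sst"]].notna().all(axis=1)
    dropped = int((~ok).sum())
    if dropped:
        log.info("extract_covariates: dropped %d record(s) on no-data cells", dropped)
    return out[ok].reset_index(drop=True)


def _term_design(df: pd.DataFrame, name) -> np.ndarray:
    """Constraint-absorbed basis for one candidate smooth term."""
    term = TensorTerm(tuple(name)) if isinstance(name, (tuple, list)) else SmoothTerm(name)
    return term.prepare(df)


def pairwise_concurvity(df: pd.DataFrame, term_names) -> pd.DataFrame:
    """Worst-case concurvity between every ordered pair of smooth terms.

    For terms i, j with (column-centred) bases Xi, Xj, the measure is the
    largest squared canonical correlation between their column spans: the
    share of the worst-affected direction of span(Xi) reproducible by a
    projection onto span(Xj).  1 means some fit of term i lies entirely in
    term j's span.
    """
    designs = {}
    for name in term_names:
        X = _term_design(df, name)
        X = X - X.mean(axis=0)
        Q, R = np.linalg.qr(X)
        keep = np.abs(np.diag(R)) > 1e-8 * max(np.abs(np.diag(R)).max(), 1e-300)
        designs[_label(name)] = Q[:, keep]
    labels = list(designs)
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for a, b in combinations(labels, 2):
        s = np.linalg.svd(designs[a].T @ designs[b], compute_uv=False)
        c = float(min(s.max() ** 2, 1.0)) if s.size else 0.0
        out.loc[a, b] = out.loc[b, a] = c
    return out


def _label(name) -> str:
    return ":".join(name) if isinstance(name, (tuple, list)) else name


def concurvity_screen(df: pd.DataFrame, term_names, threshold: float = 0.9,
                      drop_first: str = "dist_colony") -> list:
    """Drop smooth terms whose pairwise concurvity exceeds ``threshold``.

    A computed covariate listed as ``drop_first`` (distance to the colony,
    itself a function of lon/lat) is evaluated and removed first when
    flagged; remaining flagged pairs drop the later-listed term.
    """
    if len(term_names) < 2:
        raise ValueError("need at least two candidate terms")
    names = list(term_names)
    conc = pairwise_concurvity(df, names)
    labels = [_label(n) for n in names]

    def flagged(lbls):
        return [l for l in lbls if any(conc.loc[l, m] > threshold for m in lbls if m != l)]

    if drop_first in labels and drop_first in flagged(labels):
        log.info("concurvity_screen: dropping %s (concurvity > %.2f)", drop_first, threshold)
        k = labels.index(drop_first)
        del labels[k], names[k]
    while True:
        bad = flagged(labels)
        if not bad:
            break
        victim = bad[-1]
        log.info("concurvity_screen: dropping %s (concurvity > %.2f)", victim, threshold)
        k = labels.index(victim)
        del labels[k], names[k]
    return names


def _make_terms(smooths, spatial) -> list:
    terms: list = [SmoothTerm(s) for s in smooths]
    if spatial:
        terms.append(TensorTerm(tuple(spatial)))
    return terms


def fit_gam(records: pd.DataFrame, smooths=DEFAULT_SMOOTHS, spatial=SPATIAL_TERM,
            year_fixed: bool = True, **gam_kw) -> GamFit:
    """Fit the binomial GAM: 1-D smooths + lon/lat surface + year factor."""
    model = BinomialGam(_make_terms(smooths, spatial),
                        factor="year" if year_fixed else None, **gam_kw)
    return model.fit(records, records["label"].to_numpy())


def select_model(records: pd.DataFrame, smooths=DEFAULT_SMOOTHS, spatial=SPATIAL_TERM,
                 year_fixed: bool = True, **gam_kw) -> SelectionResult:
    """All-subsets AICc selection over the smooth terms (year always kept).

    Fits every subset of {1-D smooths} x {with/without the spatial term},
    ranks by AICc and reports Delta-AICc and Akaike weights
    w = exp(-Delta/2) / sum exp(-Delta/2).
    """
    candidates = []
    pool = list(smooths) + ([tuple(spatial)] if spatial else [])
    for r in range(len(pool) + 1):
        candidates.extend(combinations(pool, r))
    fits: dict[frozenset, GamFit] = {}
    rows = []
    for cand in candidates:
        sm = [c for c in cand if isinstance(c, str)]
        sp = next((c for c in cand if isinstance(c, tuple)), None)
        model = BinomialGam(_make_terms(sm, sp), factor="year" if year_fixed else None, **gam_kw)
        fit = model.fit(records, records["label"].to_numpy())
        key = frozenset(_label(c) for c in cand)
        fits[key] = fit
        row = {_label(c): "+" for c in cand}
        row.update({"year": "+" if year_fixed else "", "df": fit.edf,
                    "AICc": fit.aicc, "dev_explained": fit.deviance_explained})
        rows.append((key, row))
    table = pd.DataFrame([r for _, r in rows], index=[" + ".join(sorted(k)) or "(null)" for k, _ in rows])
    flag_cols = [_label(c) for c in pool]
    for c in flag_cols:
        if c not in table:
            table[c] = ""
    table = table.fillna({c: "" for c in flag_cols})
    table["delta"] = table["AICc"] - table["AICc"].min()
    w = np.exp(-table["delta"] / 2.0)
    table["w"] = w / w.sum()
    table = table.sort_values("AICc", kind="stable")
    table = table[["year"] + flag_cols + ["df", "AICc", "delta", "w", "dev_explained"]]
    best_key = min(fits, key=lambda k: fits[k].aicc)
    return SelectionResult(best=fits[best_key], table=table, fits=fits)


def predict_daily(fit: GamFit, env: EnvStack, domain: Domain,
                  dates=None, year="mean") -> HSIMaps:
    """Daily HSI rasters over the domain, plus mean and SD summaries.

    Per date, the model is evaluated at every domain cell centroid with
    that date's SST layer; the year fixed effect is averaged over levels
    for a pooled map (``year="mean"``) or fixed to one level.  Covariates
    are clamped to their training range inside the spline bases.
    """
    dates = list(dates) if dates is not None else env.dates
    cells = domain.cells()
    lon2d, lat2d = env.grid.cell_centres()
    base = pd.DataFrame({
        "lon": lon2d[cells], "lat": lat2d[cells],
        "bathy": env.bathy.data[cells], "slope": env.slope.data[cells],
    })
    daily = np.full((len(dates), *cells.shape), np.nan)
    for t, date in enumerate(dates):
        df = base.copy()
        df["sst"] = env.sst_on(date).data[cells]
        ok = df.notna().all(axis=1).to_numpy()
        pred = np.full(len(df), np.nan)
        if ok.any():
            pred[ok] = fit.predict(df[ok], year=year)
        layer = np.full(cells.shape, np.nan)
        layer[cells] = pred
        daily[t] = layer
    mean = np.full(cells.shape, np.nan)
    sd = np.full(cells.shape, np.nan)
    stack = daily[:, cells]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels
        mean[cells] = np.nanmean(stack, axis=0)
        sd[cells] = np.nanstd(stack, axis=0)  # population SD over days
    return HSIMaps(dates=dates, daily=daily,
                   mean=env.grid.like(mean), sd=env.grid.like(sd))


def summarize_hsi(daily: np.ndarray, grid: Grid) -> tuple[Grid, Grid]:
    """Pixel-wise arithmetic mean and population SD of a daily HSI stack."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels
        return grid.like(np.nanmean(daily, axis=0)), grid.like(np.nanstd(daily, axis=0))
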