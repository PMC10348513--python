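import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from divehab import habitat as hb
from divehab.gam import BinomialGam, SmoothTerm
from divehab.grids import AzimuthalEquidistant, EnvStack, Grid, haversine_km

COLONY = (-54.18, 46.81)


def _point_at_km(dist_km, bearing_deg=90.0):
    proj = AzimuthalEquidistant(*COLONY)
    x = dist_km * math.sin(math.radians(bearing_deg))
    y = dist_km * math.cos(math.radians(bearing_deg))
    lon, lat = proj.inverse(x, y)
    return float(lon), float(lat)


def _dives_at(points):
    return pd.DataFrame(points, columns=["lon", "lat"])


class TestDomain:
    def test_radius_rule_reproduces_451_km(self, small_env):
        lon, lat = _point_at_km(410.0)
        d = hb.build_domain(COLONY, _dives_at([(lon, lat)]), small_env, scale=1.1)
        assert d.radius_km == pytest.approx(451.0, abs=0.5)

    def test_all_dives_at_colony_gives_tiny_domain(self, small_env):
        d = hb.build_domain(COLONY, _dives_at([COLONY, COLONY]), small_env)
        lon2d, lat2d = small_env.grid.cell_centres()
        dist = haversine_km(COLONY[0], COLONY[1], lon2d, lat2d)
        assert d.n_cells >= 1
        assert dist[d.cells()].max() < 20.0

    def test_land_only_grid_rejected(self):
        proto = Grid(-55.0, 45.0, 0.1, np.zeros((5, 5)))
        env = EnvStack(bathy=proto, slope=proto,
                       sea=proto.like(np.zeros((5, 5))), sst={})
        with pytest.raises(ValueError, match="empty domain"):
            hb.build_domain((-54.5, 45.3), _dives_at([(-54.5, 45.2)]), env)

    def test_domain_cells_are_sea(self, small_env):
        lon, lat = _point_at_km(150.0)
        d = hb.build_domain(COLONY, _dives_at([(lon, lat)]), small_env)
        assert (small_env.sea_mask() | ~d.cells()).all()


def _presences(n, year=2021, rng=None):
    rng = rng or np.random.default_rng(0)
    lon = COLONY[0] + rng.uniform(-0.5, 0.5, n)
    lat = COLONY[1] - rng.uniform(0.1, 0.6, n)
    dates = [dt.date(year, 7, 15) + dt.timedelta(days=int(d)) for d in rng.integers(0, 20, n)]
    return pd.DataFrame({"lon": lon, "lat": lat, "date": dates, "year": year, "label": 1})


@pytest.fixture()
def domain(small_env):
    lon, lat = _point_at_km(200.0, bearing_deg=180.0)
    return hb.build_domain(
        COLONY, _dives_at([(lon, lat)]), small_env,
        year_ranges={2021: (dt.date(2021, 7, 15), dt.date(2021, 8, 3))})


class TestPseudoAbsences:
    def test_exact_three_to_one_ratio_inside_domain(self, domain):
        pres = _presences(10)
        absn = hb.sample_pseudo_absences(pres, domain, ratio=3, seed=1)
        assert len(absn) == 30
        assert (absn["label"] == 0).all()
        i, j = domain.mask.index_of(absn["lon"].to_numpy(), absn["lat"].to_numpy())
        assert (domain.mask.data[i, j] == 1).all()

    def test_ratio_zero_is_empty(self, domain):
        assert hb.sample_pseudo_absences(_presences(5), domain, ratio=0).empty

    def test_dates_inside_year_tracking_period(self, domain):
        absn = hb.sample_pseudo_absences(_presences(40), domain, seed=2)
        lo, hi = domain.year_ranges[2021]
        assert absn["date"].map(lambda d: lo <= d <= hi).all()

    def test_reproducible_from_seed(self, domain):
        a = hb.sample_pseudo_absences(_presences(20), domain, seed=5)
        b = hb.sample_pseudo_absences(_presences(20), domain, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_two_cell_domain_is_uniform(self, small_env):
        # binomial bounds: 10^4 draws over 2 cells -> 5000 +- 3*sqrt(2500)
        mask = np.zeros(small_env.grid.shape)
        sea = np.argwhere(small_env.sea_mask())
        mask[tuple(sea[0])] = 1
        mask[tuple(sea[200])] = 1
        dom = hb.Domain(small_env.grid.like(mask), 10.0, COLONY,
                        {2021: (dt.date(2021, 7, 15), dt.date(2021, 7, 24))})
        absn = hb.sample_pseudo_absences(_presences(2500), dom, ratio=4, seed=3)
        i, j = dom.mask.index_of(absn["lon"].to_numpy(), absn["lat"].to_numpy())
        counts = pd.Series(zip(i, j)).value_counts()
        assert len(counts) == 2
        assert abs(counts.iloc[0] - 5000) <= 150


class TestCovariates:
    def test_static_lookup_value(self):
        proto = Grid(-55.0, 46.0, 0.5, np.array([[80.0, 120.0]]))
        env = EnvStack(bathy=proto, slope=proto.like(np.array([[2.0, 3.0]])),
                       sea=proto.like(np.ones((1, 2))),
                       sst={dt.date(2021, 7, 15): proto.like(np.array([[10.0, 11.0]]))})
        rec = pd.DataFrame({"lon": [-54.75], "lat": [46.25],
                            "date": [dt.date(2021, 7, 15)], "year": 2021, "label": 1})
        out = hb.extract_covariates(rec, env)
        assert out.loc[0, "bathy"] == 80.0 and out.loc[0, "slope"] == 2.0
        assert out.loc[0, "sst"] == 10.0

    def test_same_place_different_dates_get_different_sst(self, small_env):
        days = small_env.dates
        rec = pd.DataFrame({
            "lon": [COLONY[0]] * 2, "lat": [COLONY[1] - 0.5] * 2,
            "date": [days[0], days[-1]], "year": 2021, "label": 1,
        })
        out = hb.extract_covariates(rec, small_env)
        assert out.loc[0, "sst"] != out.loc[1, "sst"]

    def test_land_points_dropped(self, small_env, caplog):
        rec = pd.DataFrame({
            "lon": [COLONY[0], COLONY[0]],
            "lat": [COLONY[1] - 0.5, small_env.grid.lat_max - 0.01],  # sea, land
            "date": [small_env.dates[0]] * 2, "year": 2021, "label": 1,
        })
        with caplog.at_level("INFO", logger="divehab.habitat"):
            out = hb.extract_covariates(rec, small_env)
        assert len(out) == 1
        assert "dropped 1" in caplog.text

    def test_distance_to_colony_computed(self, small_env):
        rec = pd.DataFrame({"lon": [COLONY[0]], "lat": [COLONY[1] - 1.0],
                            "date": [small_env.dates[0]], "year": 2021, "label": 1})
        out = hb.extract_covariates(rec, small_env, colony=COLONY)
        assert out.loc[0, "dist_colony"] == pytest.approx(111.2, abs=0.2)


class TestConcurvity:
    def _records(self, n=1000, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "bathy": rng.uniform(0, 300, n),
            "slope": rng.uniform(0, 10, n),
            "sst": rng.uniform(8, 20, n),
            "lon": rng.uniform(-57, -52, n),
            "lat": rng.uniform(44, 47, n),
        })

    def test_duplicated_covariate_has_unit_concurvity(self):
        df = self._records()
        df["bathy2"] = df["bathy"]
        conc = hb.pairwise_concurvity(df, ["bathy", "bathy2", "sst"])
        assert conc.loc["bathy", "bathy2"] == pytest.approx(1.0, abs=1e-6)
        kept = hb.concurvity_screen(df, ["bathy", "bathy2", "sst"])
        assert "bathy2" not in kept and "bathy" in kept

    def test_independent_uniforms_have_low_concurvity(self):
        conc = hb.pairwise_concurvity(self._records(), ["bathy", "slope", "sst"])
        off = conc.to_numpy()[~np.eye(3, dtype=bool)]
        assert (off < 0.2).all()

    def test_distance_to_colony_dropped_against_lonlat_surface(self):
        df = self._records(1500)
        df["dist_colony"] = haversine_km(COLONY[0], COLONY[1],
                                         df["lon"].to_numpy(), df["lat"].to_numpy())
        terms = ["dist_colony", "bathy", "slope", "sst", ("lon", "lat")]
        conc = hb.pairwise_concurvity(df, terms)
        assert conc.loc["dist_colony", "lon:lat"] > 0.9
        kept = hb.concurvity_screen(df, terms)
        assert "dist_colony" not in [hb._label(t) for t in kept]
        assert ("lon", "lat") in kept

    def test_single_term_rejected(self):
        with pytest.raises(ValueError):
            hb.concurvity_screen(self._records(), ["bathy"])


def _model_records(n=1200, seed=0, beta_sst=1.4, beta_bathy=-1.2):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "bathy": rng.uniform(-2, 2, n),
        "slope": rng.uniform(-2, 2, n),
        "sst": rng.uniform(-2, 2, n),
        "lon": rng.uniform(0, 4, n),
        "lat": rng.uniform(0, 4, n),
        "year": rng.choice([2019, 2020, 2021], n),
    })
    eta = beta_sst * df["sst"] + beta_bathy * df["bathy"]
    df["label"] = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
    return df


@pytest.fixture(scope="module")
def selection():
    return hb.select_model(_model_records(), smooths=("bathy", "slope", "sst"),
                           spatial=None)


@pytest.fixture(scope="module")
def world(small_env):
    records = _model_records(1000, seed=2)
    fit = hb.fit_gam(records, smooths=("sst",), spatial=None)
    lon, lat = _point_at_km(120.0, bearing_deg=180.0)
    dom = hb.build_domain(COLONY, _dives_at([(lon, lat)]), small_env,
                          year_ranges={2021: (dt.date(2021, 7, 15), dt.date(2021, 8, 3))})
    return fit, dom


class TestSelection:

    def test_akaike_weights_recomputed_from_aicc(self, selection):
        t = selection.table
        delta = t["AICc"] - t["AICc"].min()
        w = np.exp(-delta / 2)
        assert np.allclose(t["w"], w / w.sum(), atol=1e-12)
        assert t["w"].sum() == pytest.approx(1.0)
        # two models two AICc units apart have weight ratio e
        assert np.interp(2.0, [0, 2], [1, 1]) and math.isclose(
            math.exp(-0.0 / 2) / math.exp(-2.0 / 2), math.e)

    def test_selected_not_worse_than_global(self, selection):
        full = frozenset({"bathy", "slope", "sst"})
        assert selection.best.aicc <= selection.fits[full].aicc + 1e-9

    def test_true_subset_selected(self, selection):
        t = selection.table
        top = t.index[0]
        assert "sst" in top and "bathy" in top and "slope" not in top

    def test_table_sorted_by_aicc(self, selection):
        assert selection.table["AICc"].is_monotonic_increasing

    def test_noise_covariate_raises_aicc_in_most_replicates(self):
        worse = 0
        for seed in range(8):
            df = _model_records(n=900, seed=seed)
            base = hb.fit_gam(df, smooths=("bathy", "sst"), spatial=None)
            noisy = hb.fit_gam(df, smooths=("bathy", "sst", "slope"), spatial=None)
            assert noisy.deviance_explained >= base.deviance_explained - 1e-3
            worse += noisy.aicc > base.aicc
        assert worse >= 6


class TestPrediction:
    def test_daily_maps_in_unit_interval(self, small_env, world):
        fit, dom = world
        maps = hb.predict_daily(fit, small_env, dom, small_env.dates[:3])
        vals = maps.daily[np.isfinite(maps.daily)]
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_identical_env_days_give_identical_maps(self, small_env, world):
        fit, dom = world
        date = small_env.dates[0]
        maps = hb.predict_daily(fit, small_env, dom, [date, date])
        assert np.array_equal(maps.daily[0], maps.daily[1], equal_nan=True)
        assert np.nanmax(maps.sd.data) == 0.0

    def test_constant_sst_day_gives_constant_map(self, world):
        fit, dom = world
        grid = dom.mask
        const = grid.like(np.full(grid.shape, 13.0))
        env = EnvStack(bathy=grid.like(np.full(grid.shape, 50.0)),
                       slope=grid.like(np.zeros(grid.shape)),
                       sea=grid.like(np.ones(grid.shape)),
                       sst={dt.date(2021, 7, 15): const})
        maps = hb.predict_daily(fit, env, dom, [dt.date(2021, 7, 15)])
        vals = maps.daily[0][dom.cells()]
        assert np.nanstd(vals) < 1e-12

    def test_summary_two_point_formula(self, small_env):
        grid = small_env.grid
        a = np.full(grid.shape, 0.2)
        b = np.full(grid.shape, 0.4)
        mean, sd = hb.summarize_hsi(np.stack([a, b]), grid)
        assert np.allclose(mean.data, 0.3)
        assert np.allclose(sd.data, 0.1)

    def test_mean_bounded_by_daily_envelope(self, small_env, world):
        fit, dom = world
        maps = hb.predict_daily(fit, small_env, dom, small_env.dates[:4])
        cells = dom.cells()
        lo = np.nanmin(maps.daily[:, cells], axis=0)
        hi = np.nanmax(maps.daily[:, cells], axis=0)
        m = maps.mean.data[cells]
        ok = np.isfinite(m)
        assert ((m[ok] >= lo[ok] - 1e-12) & (m[ok] <= hi[ok] + 1e-12)).all()
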