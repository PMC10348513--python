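"""End-to-end pipeline: simulate (or load) -> dives -> contingency ->
utilization distributions -> habitat models -> daily HSI maps.

Each run writes its artifacts plus a manifest (parameters, derived
per-stage seeds, per-stage record counts) sufficient to re-run any stage
bit-identically.  A stage failure raises a stage-tagged error; partial
outputs are retained next to a FAILED marker file.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dives as dv
from . import habitat as hb
from . import io as dio
from . import spaceuse as su
from . import stats as st
from .simulate import SimConfig, gen_environment, gen_tracks_and_dives

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("divehab.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything one run needs.  Exactly one of ``sim`` (synthetic world)
    or ``inputs`` (paths to GPS/TDR CSVs + env directory) must be set.
    Defaults mirror the field-standard processing parameters: 0.5 m surface
    threshold, 1 m depth filter, U rule (3 s, 10 s, 8 m), 30-min foraging
    window, 3:1 pseudo-absences, 1.1 domain scale, h = 2 ln(range),
    concurvity threshold 0.9."""

    sim: SimConfig | None = None
    inputs: dict | None = None  # {"fixes": path, "traces": path, "env": dir}
    out_dir: str | Path = "pipeline_out"
    master_seed: int = 0
    surface_threshold: float = 0.5
    bottom_frac: float = 0.8
    classifier_rule: str = "or"
    window_s: float = 1800.0
    cutoff: dv.CutoffRule = field(default_factory=dv.CutoffRule)
    pseudo_absence_ratio: int = 3
    domain_scale: float = 1.1
    ud_levels: tuple[float, ...] = (0.5, 0.95)
    ud_cell_km: float = 1.0
    concurvity_threshold: float = 0.9
    dive_types: tuple[str, ...] = ("U", "V-early", "V-late")
    select: bool = True
    write_outputs: bool = True

    def __post_init__(self):
        if (self.sim is None) == (self.inputs is None):
            raise ValueError("exactly one of sim / inputs must be configured")
        if not (0 < self.surface_threshold < dv.MIN_DEPTH_M):
            raise ValueError("surface threshold must lie in (0, 1) m")
        if self.pseudo_absence_ratio < 0:
            raise ValueError("pseudo-absence ratio must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "sim" in raw and raw["sim"] is not None:
            sim = raw["sim"]
            if "date_range" in sim:
                sim["date_range"] = tuple(pd.Timestamp(d).date() for d in sim["date_range"])
            if "colony" in sim:
                sim["colony"] = tuple(sim["colony"])
            raw["sim"] = SimConfig(**sim)
        if "cutoff" in raw:
            raw["cutoff"] = dv.CutoffRule(**raw["cutoff"])
        return cls(**raw)


def _stage_seeds(master: int, names) -> dict[str, int]:
    seqs = np.random.SeedSequence(master).spawn(len(names))
    return {n: int(s.generate_state(1)[0] % (2 ** 31)) for n, s in zip(names, seqs)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a result bundle (dict) and writes artifacts.

    Bundle keys: env, fixes, traces, truth (synthetic runs), events,
    contingency, cutoffs, ud (per dive type), hsm (per dive type),
    manifest.
    """
    out = Path(config.out_dir)
    if config.write_outputs:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "master_seed": config.master_seed,
        "parameters": {
            "surface_threshold": config.surface_threshold,
            "bottom_frac": config.bottom_frac,
            "classifier_rule": config.classifier_rule,
            "window_s": config.window_s,
            "pseudo_absence_ratio": config.pseudo_absence_ratio,
            "domain_scale": config.domain_scale,
            "concurvity_threshold": config.concurvity_threshold,
            "ud_levels": list(config.ud_levels),
        },
        "counts": {},
        "stages": [],
    }
    seeds = _stage_seeds(config.master_seed, ["simulate", "pseudo_absence"])
    manifest["seeds"] = seeds
    bundle: dict = {"manifest": manifest}

    def fail(stage, exc):
        if config.write_outputs:
            (out / "FAILED").write_text(f"{stage}: {exc}\n")
        raise PipelineError(stage, str(exc)) from exc

    # -- inputs ---------------------------------------------------------
    try:
        if config.sim is not None:
            sim = config.sim
            if sim.seed != seeds["simulate"]:
                sim = SimConfig(**{**sim.__dict__, "seed": seeds["simulate"],
                                   "u_fraction_by_day": sim.u_fraction_by_day})
            env = gen_environment(sim)
            fixes, traces, truth = gen_tracks_and_dives(sim, env)
            colony = sim.colony
            bundle["truth"] = truth
        else:
            fixes = dio.read_fixes(config.inputs["fixes"])
            traces = dio.read_traces(config.inputs["traces"])
            env = dio.read_env(config.inputs["env"])
            colony = tuple(config.inputs["colony"])
            if "trip_id" not in fixes:
                fixes["trip_id"] = fixes["bird_id"]
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage-tagged re-raise
        fail("inputs", exc)
    bundle.update(env=env, fixes=fixes, traces=traces, colony=colony)
    manifest["counts"]["fixes"] = len(fixes)
    manifest["counts"]["trace_samples"] = len(traces)
    manifest["stages"].append("inputs")

    # -- dive processing ------------------------------------------------
    try:
        events = dv.process_traces(traces, config.surface_threshold,
                                   config.bottom_frac, config.classifier_rule)
        if events.empty:
            raise ValueError("no dives survived detection + 1 m filter")
        events = dv.assign_foraging_locations(events, fixes, config.window_s)
        cutoffs = dv.detect_cutoff(events, config.cutoff)
        events = dv.phase_labels(events, cutoffs)
    except PipelineError:
        raise
    except Exception as exc:
        fail("dive_processing", exc)
    bundle.update(events=events, cutoffs=cutoffs)
    manifest["counts"]["dives"] = len(events)
    manifest["counts"]["dives_by_shape"] = events["shape"].value_counts().to_dict()
    manifest["counts"]["dives_with_location"] = int(events["lon"].notna().sum())
    manifest["cutoffs"] = {y: d.isoformat() for y, d in cutoffs.items()}
    manifest["stages"].append("dive_processing")

    # -- contingency ----------------------------------------------------
    try:
        observed = st.build_table(events)
        if observed.empty:
            raise ValueError("empty contingency table")
        # the chi-square test needs >= 2 rows; single-year runs skip it
        contingency = (st.chi_square_independence(observed)
                       if observed.shape[0] >= 2 else None)
    except PipelineError:
        raise
    except Exception as exc:
        fail("dive_stats", exc)
    bundle.update(observed=observed, contingency=contingency)
    if contingency is not None:
        manifest["chi2"] = {"statistic": contingency.chi2, "df": contingency.df,
                            "p_value": contingency.p_value}
    manifest["stages"].append("dive_stats")

    # -- space use ------------------------------------------------------
    try:
        mean_range = su.foraging_range(fixes, colony)
        h = su.smoothing_scale(mean_range)
        located = events[events["lon"].notna()]
        uds = {}
        for dtp in config.dive_types:
            sel = _select_type(located, dtp)
            if len(sel) >= 5:
                uds[dtp] = su.kde_ud(sel["lon"], sel["lat"], colony, h,
                                     cell_km=config.ud_cell_km)
    except PipelineError:
        raise
    except Exception as exc:
        fail("space_use", exc)
    bundle.update(ud=uds, mean_range_km=mean_range, h_km=h)
    manifest["mean_foraging_range_km"] = mean_range
    manifest["h_km"] = h
    manifest["stages"].append("space_use")

    # -- habitat models -------------------------------------------------
    try:
        located = events[events["lon"].notna()].copy()
        located["date"] = pd.to_datetime(located["start_time"]).dt.date
        domain = hb.build_domain(colony, located.rename(columns={"start_time": "timestamp"}),
                                 env, config.domain_scale)
        rng = np.random.default_rng(seeds["pseudo_absence"])
        hsm = {}
        for dtp in config.dive_types:
            pres = _select_type(located, dtp)[["lon", "lat", "date", "year"]].copy()
            if len(pres) < 50:
                log.info("skipping habitat model for %s (only %d presences)", dtp, len(pres))
                continue
            pres["label"] = 1
            absn = hb.sample_pseudo_absences(pres, domain, config.pseudo_absence_ratio, rng)
            data = hb.extract_covariates(pd.concat([pres, absn], ignore_index=True),
                                         env, colony=colony)
            candidates = ["dist_colony", "bathy", "slope", "sst", ("lon", "lat")]
            kept = hb.concurvity_screen(data, candidates, config.concurvity_threshold)
            smooths = [t for t in kept if isinstance(t, str)]
            spatial = next((t for t in kept if isinstance(t, tuple)), None)
            if config.select:
                sel = hb.select_model(data, smooths, spatial)
                fit, table = sel.best, sel.table
            else:
                fit, table = hb.fit_gam(data, smooths, spatial), None
            maps = hb.predict_daily(fit, env, domain, _dates_for(dtp, cutoffs, env))
            hsm[dtp] = {"fit": fit, "selection": table, "maps": maps,
                        "n_presence": len(pres), "n_absence": len(absn)}
            manifest["counts"][f"presences_{dtp}"] = len(pres)
            manifest["counts"][f"pseudo_absences_{dtp}"] = len(absn)
    except PipelineError:
        raise
    except Exception as exc:
        fail("habitat_model", exc)
    bundle.update(domain=domain, hsm=hsm)
    manifest["counts"]["domain_cells"] = domain.n_cells
    manifest["stages"].append("habitat_model")

    if config.write_outputs:
        _write_bundle(out, config, bundle)
    return bundle


def _select_type(events: pd.DataFrame, dive_type: str) -> pd.DataFrame:
    if dive_type == "U":
        return events[events["shape"] == "U"]
    phase = dive_type.split("-", 1)[1]
    return events[(events["shape"] == "V") & (events["phase"] == phase)]


def _dates_for(dive_type: str, cutoffs: dict, env) -> list[dt.date]:
    """Predict within the dive type's own time span (early/late split)."""
    dates = env.dates
    if dive_type == "V-early":
        return [d for d in dates if any(d < c for c in cutoffs.values())] or dates
    if dive_type == "V-late":
        return [d for d in dates if any(d >= c for c in cutoffs.values())] or dates
    return dates


def _write_bundle(out: Path, config: PipelineConfig, bundle: dict) -> None:
    dio.write_fixes(bundle["fixes"], out / "fixes.csv")
    dio.write_traces(bundle["traces"], out / "traces.csv")
    dio.write_events(bundle["events"], out / "dive_events.csv")
    if bundle.get("observed") is not None and not bundle["observed"].empty:
        bundle["observed"].to_csv(out / "contingency_observed.csv")
    if bundle.get("contingency") is not None:
        bundle["contingency"].to_frame().to_csv(out / "contingency_cells.csv", index=False)
    for dtp, ud in bundle.get("ud", {}).items():
        su.write_geojson(out / f"ud_{dtp}.geojson",
                         su.isopleth_geojson(ud, config.ud_levels))
    for dtp, h in bundle.get("hsm", {}).items():
        if h["selection"] is not None:
            h["selection"].to_csv(out / f"selection_{dtp}.csv")
        from .grids import write_ascii_grid
        write_ascii_grid(out / f"hsi_mean_{dtp}.asc", h["maps"].mean)
        write_ascii_grid(out / f"hsi_sd_{dtp}.asc", h["maps"].sd)
    dio.write_json(bundle["manifest"], out / "manifest.json")
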