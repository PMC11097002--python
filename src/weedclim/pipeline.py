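"""End-to-end orchestration with config, logging and provenance.

``run_all`` executes the full analysis — simulate (or load) the world,
ingest and clean occurrences, enrich with lagged environment, summarize
per species, fit elevation and coupling trends, cross-reference host
crops, and run windowed PCA — writing every table the downstream
figures and tables need plus a manifest that reconciles row counts at
every stage.  Given the same seed the numeric outputs are byte
identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__
from .coupling import CouplingConfig, species_association
from .errors import ConfigError, DataError
from .extraction import enrich
from .grids import MonthlyGrid, index_to_month, month_index
from .hosts import DEFAULT_HOST_MAP, presence_report
from .occurrences import clean_occurrences, read_occurrences
from .stats import anova_tukey_letters
from .synthetic import (ScenarioConfig, default_scenario, generate_crop_grids,
                        generate_env_grids, generate_occurrences)
from .trends import (build_location_series, classify_all_locations,
                     elevation_trend, location_env_trends, windowed_pca)

log = logging.getLogger("weedclim")

_FLOAT_FMT = "%.10g"

#: environmental summary tables: output label -> (column, completeness column)
SUMMARY_VARIABLES = {
    "lst_lag1_c": ("lst_c_lag1", "complete_temperature"),
    "lst_lag2_c": ("lst_c_lag2", "complete_temperature"),
    "lst_lag1_pctile": ("lst_pctile_lag1", "complete_temperature"),
    "lst_lag2_pctile": ("lst_pctile_lag2", "complete_temperature"),
    "rzsm_lag1_pct": ("rzsm_pct_lag1", "complete_moisture"),
    "rzsm_lag2_pct": ("rzsm_pct_lag2", "complete_moisture"),
    "elevation_m": ("elevation_m", None),
}


@dataclass
class RunConfig:
    """Parameterization of a full pipeline run.

    In simulate mode ``scenario`` drives everything; in file mode the
    occurrence table and grid paths must all exist (checked before any
    computation starts).
    """

    output_dir: str = "weedclim_run"
    seed: int = 0
    scenario: ScenarioConfig | None = None
    occurrences_path: str | None = None
    lst_path: str | None = None
    rzsm_path: str | None = None
    elev_path: str | None = None
    crop_paths: dict | None = None        # epoch -> netcdf path
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    alpha: float = 0.05
    trend_elevation_cutoff_m: float = 1000.0   # strict (>)
    host_elevation_cutoff_m: float = 1000.0    # inclusive (>=)
    focal_species: str = "Striga asiatica"
    pca_windows: tuple = ((2006, 2017), (2018, 2022))
    host_map: dict = field(default_factory=lambda: dict(DEFAULT_HOST_MAP))

    def __post_init__(self):
        if isinstance(self.scenario, dict):
            self.scenario = ScenarioConfig(**self.scenario)
        if isinstance(self.coupling, dict):
            self.coupling = CouplingConfig(**self.coupling)
        self.pca_windows = tuple(tuple(w) for w in self.pca_windows)
        if self.scenario is None:
            needed = [self.occurrences_path, self.lst_path, self.rzsm_path,
                      self.elev_path]
            if any(p is None for p in needed):
                raise ConfigError("file mode needs occurrences_path and "
                                  "lst/rzsm/elev grid paths (or a scenario)")
            missing = [str(p) for p in needed if not Path(p).exists()]
            if self.crop_paths:
                missing += [str(p) for p in self.crop_paths.values()
                            if not Path(p).exists()]
            if missing:
                raise ConfigError(f"missing input paths: {', '.join(missing)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "scenario" in d and d["scenario"] is not None:
            d["scenario"] = ScenarioConfig(**d["scenario"])
        return cls(**d)

    def config_hash(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)
        blob = json.dumps(asdict_safe(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def asdict_safe(cfg: RunConfig) -> dict:
    d = dict(cfg.__dict__)
    d.pop("output_dir", None)   # location metadata, not analysis parameters
    if cfg.scenario is not None:
        d["scenario"] = asdict(cfg.scenario)
    d["coupling"] = cfg.coupling.as_dict()
    return d


# ----------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def _crops_to_netcdf(layers: dict, path: Path) -> None:
    ds = xr.Dataset({crop: g.to_dataset()[g.variable.lower()].rename(crop)
                     for crop, g in layers.items()})
    ds.to_netcdf(path, engine="scipy")


def crops_from_netcdf(path) -> dict:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    return {name: MonthlyGrid("CROP_AREA", ds[name].lon.values,
                              ds[name].lat.values, ds[name].values)
            for name in ds.data_vars}


class _Stage:
    """Context that renames any failure to its pipeline stage."""

    def __init__(self, name: str, manifest: dict):
        self.name = name
        self.manifest = manifest

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is not None:
            log.error("stage %-12s FAILED after %.1fs: %s", self.name, dt, exc)
            if exc_type not in (ConfigError, DataError):
                raise DataError(f"stage {self.name!r} failed: {exc}") from exc
            exc.args = (f"stage {self.name!r}: {exc}",)
            return False
        log.info("stage %-12s done in %.1fs", self.name, dt)
        return False

    def count(self, **counts):
        self.manifest["stages"].setdefault(self.name, {}).update(counts)


def run_all(config: RunConfig) -> Path:
    """Execute every stage and return the artifact directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict_safe(config),
        "config_hash": config.config_hash(),
        "versions": {"weedclim": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "stages": {},
    }

    # -- world ---------------------------------------------------------
    with _Stage("simulate", manifest) as st:
        if config.scenario is not None:
            scen = config.scenario
            grids = generate_env_grids(scen)
            raw = generate_occurrences(scen, grids)
            crops = generate_crop_grids(scen, grids["elev"])
            scen.to_yaml(out / "scenario.yaml")
            for name in ("lst", "rzsm", "elev"):
                grids[name].to_netcdf(out / f"{name}.nc")
            for epoch, layers in crops.items():
                _crops_to_netcdf(layers, out / f"crops_{epoch}.nc")
            _write_csv(raw, out / "occurrences_raw.csv")
            raw = read_occurrences(out / "occurrences_raw.csv")
        else:
            raw = read_occurrences(config.occurrences_path)
            grids = {name: MonthlyGrid.from_netcdf(p) for name, p in
                     (("lst", config.lst_path), ("rzsm", config.rzsm_path),
                      ("elev", config.elev_path))}
            crops = ({int(e): crops_from_netcdf(p)
                      for e, p in config.crop_paths.items()}
                     if config.crop_paths else {})
        st.count(raw_records=len(raw))

    # -- ingest --------------------------------------------------------
    with _Stage("ingest", manifest) as st:
        clean, report = clean_occurrences(raw)
        report.to_json(out / "cleaning_report.json")
        _write_csv(clean, out / "occurrences_clean.csv")
        st.count(input=report.n_input, retained=report.n_retained,
                 dropped=report.n_input - report.n_retained)

    # -- enrich --------------------------------------------------------
    with _Stage("enrich", manifest) as st:
        enriched = enrich(clean, grids["lst"], grids["rzsm"], grids["elev"])
        _write_csv(enriched, out / "enriched.csv")
        st.count(input=len(clean), enriched=len(enriched),
                 complete_temperature=int(enriched["complete_temperature"].sum()),
                 complete_moisture=int(enriched["complete_moisture"].sum()),
                 complete_coupling=int(enriched["complete_coupling"].sum()))

    # -- per-species environmental summaries ---------------------------
    with _Stage("summarize", manifest) as st:
        rows, tests = [], {}
        for label, (col, flag) in SUMMARY_VARIABLES.items():
            df = enriched if flag is None else enriched[enriched[flag]]
            groups = {sp: g[col].dropna().to_numpy(dtype=float)
                      for sp, g in df.groupby("species")}
            groups = {sp: v for sp, v in groups.items() if v.size >= 2}
            if len(groups) < 2:
                continue
            summaries, f, p, _ = anova_tukey_letters(groups, config.alpha)
            tests[label] = {"F": f, "p": p}
            for s in summaries:
                rows.append({"variable": label, "species": s.name, "n": s.n,
                             "mean": s.mean, "min": s.min, "max": s.max,
                             "q3": s.q3, "significance": s.letters})
        _write_csv(pd.DataFrame(rows), out / "env_summaries.csv")
        _write_json(tests, out / "env_summary_tests.json")
        st.count(variables=len(tests), rows=len(rows))

    # -- per-species elevation trends ----------------------------------
    with _Stage("trends", manifest) as st:
        trow = []
        for sp, g in enriched.groupby("species"):
            try:
                fit, odds = elevation_trend(
                    g, config.trend_elevation_cutoff_m, inclusive=False)
                trow.append({"species": sp, **fit.summary_row(),
                             "odds_ratio_total": odds["odds_ratio_total"],
                             "delta_probability": odds["delta_probability"]})
            except DataError as exc:
                trow.append({"species": sp, "log_odds_estimate": np.nan,
                             "note": str(exc)})
        _write_csv(pd.DataFrame(trow), out / "elevation_trends.csv")
        st.count(species=len(trow))

    # -- coupling association ------------------------------------------
    with _Stage("coupling", manifest) as st:
        assoc = species_association(enriched, config.coupling)
        assoc_out = assoc.copy()
        for k, v in config.coupling.as_dict().items():
            assoc_out[k] = [v] * len(assoc_out) if isinstance(v, list) else v
        _write_csv(assoc_out, out / "coupling_association.csv")
        st.count(species=len(assoc),
                 decidable=int(assoc["n_complete"].sum()),
                 coupled=int(assoc["n_coupled"].sum()))

    # -- per-location trends for the focal species ---------------------
    with _Stage("locations", manifest) as st:
        focal = enriched[enriched["species"] == config.focal_species]
        if focal.empty:
            raise DataError(f"no records for focal species "
                            f"{config.focal_species!r}")
        locs = build_location_series(focal, grids["lst"], grids["rzsm"],
                                     grids["elev"])
        summary, table = classify_all_locations(
            locs, config.coupling, config.trend_elevation_cutoff_m,
            config.alpha)
        mk_rows = []
        for loc in locs:
            mk = location_env_trends(loc)
            mk_rows.append({"lon": loc.lon, "lat": loc.lat,
                            "elevation_m": loc.elevation_m,
                            "tau_lst": mk["lst"].tau, "p_lst": mk["lst"].p,
                            "tau_rzsm": mk["rzsm"].tau, "p_rzsm": mk["rzsm"].p})
        table = table.merge(pd.DataFrame(mk_rows),
                            on=["lon", "lat", "elevation_m"], how="left")
        _write_csv(table, out / "location_trends.csv")
        _write_json(summary, out / "stratified_trends.json")
        # month-by-month coupling indicator matrix (heatmap analogue)
        mat = pd.DataFrame(
            [loc.coupling_series(config.coupling) for loc in locs],
            columns=[f"{y}-{m:02d}" for y, m in
                     (index_to_month(month_index(*locs[0].start) + k)
                      for k in range(locs[0].n_months))] if locs else None)
        mat.insert(0, "lon", [loc.lon for loc in locs])
        mat.insert(1, "lat", [loc.lat for loc in locs])
        _write_csv(mat, out / "coupling_matrix.csv")
        st.count(locations=len(locs))

    # -- host crops -----------------------------------------------------
    with _Stage("hosts", manifest) as st:
        if crops:
            hp = presence_report(enriched, crops, config.host_map,
                                 config.host_elevation_cutoff_m, inclusive=True)
            _write_csv(hp, out / "host_presence.csv")
            st.count(rows=len(hp))
        else:
            st.count(rows=0, note="no crop grids supplied")

    # -- windowed PCA ---------------------------------------------------
    with _Stage("pca", manifest) as st:
        pca_out = {}
        for window in config.pca_windows:
            key = f"{window[0]}-{window[1]}"
            try:
                res = windowed_pca(focal, window)
                pca_out[key] = {"variables": res.variables,
                                "loadings": res.loadings,
                                "explained": res.explained,
                                "n": int(res.scores.shape[0])}
            except DataError as exc:
                pca_out[key] = {"error": str(exc)}
        _write_json(pca_out, out / "windowed_pca.json")
        st.count(windows=len(pca_out))

    _write_json(manifest, out / "manifest.json")
    return out
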