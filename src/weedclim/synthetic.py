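"""Synthetic study world: environmental grids, occurrences and crop layers
with known planted structure.

The generator emulates the statistical skeleton of the real study
system — eight parasitic-weed species with contrasting temperature,
moisture and elevation niches observed over a 17-year span on monthly
temperature and soil-moisture-percentile grids — while planting effects
whose recovery the downstream pipeline can be tested against:

* a smooth elevation surface with a designated montane region (>1000 m);
* seasonal, lapse-rate-cooled temperature with a warming trend and a
  wetting soil-moisture trend planted only at designated (montane)
  cells, sized so the monthly heat-moisture coupling probability there
  rises from a few percent to roughly half over the span;
* species placed by importance sampling on Gaussian niche densities
  over the lag-1 environment, with a time-drifting preferred elevation
  for range-shifting species;
* two-epoch harvested-area layers for host crops, with configurable
  withdrawal of named crops above an elevation cutoff in one epoch.

One global seed drives three named substreams (environment,
occurrences, crops) so each product can be regenerated independently
and reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .grids import MonthlyGrid

__all__ = ["SpeciesNiche", "EnvTrends", "ScenarioConfig", "default_scenario",
           "generate_env_grids", "generate_occurrences", "generate_crop_grids"]

_STREAMS = {"env": 0, "occurrences": 1, "crops": 2}


@dataclass
class SpeciesNiche:
    """Gaussian environmental niche of one species.

    Means/SDs are on the observation scale: LST in degC, RZSM in
    percentile points, elevation in metres.  ``elev_trend_per_year``
    shifts the preferred elevation linearly over the study span,
    emulating an altitudinal range shift.
    """

    lst_mean: float
    lst_sd: float
    rzsm_mean: float
    rzsm_sd: float
    elev_pref_m: float
    elev_sd_m: float
    n_occurrences: int
    elev_trend_per_year: float = 0.0


@dataclass
class EnvTrends:
    """Parameters of the environmental fields.

    Temperature: sea-level baseline minus lapse-rate cooling, an annual
    sinusoid (phase flipped south of the equator), a linear warming
    trend applied at designated cells only, and iid Gaussian noise.
    Moisture is generated directly on the wetness-percentile scale
    (0-100), with a west-east gradient, a planted wetting trend at
    designated cells, and noise, clipped to [0, 100].
    """

    lst_base_c: float = 32.0            # annual-mean LST at sea level
    lapse_rate_c_per_km: float = 6.5
    seasonal_amplitude_c: float = 4.0
    lst_trend_c_per_year: float = 0.15  # at designated cells
    noise_sd: float = 1.2               # LST noise, degC
    rzsm_base_pct: float = 55.0
    rzsm_lon_gradient_pct: float = 10.0  # +/- across the domain, dry west wet east
    rzsm_trend_pct_per_year: float = 1.5  # at designated cells
    rzsm_noise_sd: float = 12.0


@dataclass
class ScenarioConfig:
    """Full parameterization of the synthetic world."""

    grid_nx: int = 20
    grid_ny: int = 20
    lon_min: float = 30.0
    lon_max: float = 40.0
    lat_min: float = -10.0
    lat_max: float = 0.0
    start_year: int = 2006
    end_year: int = 2022
    species_niches: dict = field(default_factory=dict)
    env_trends: EnvTrends = field(default_factory=EnvTrends)
    #: (iy, ix) cells carrying the planted trends; None -> all cells >1000 m.
    designated_cells: list | None = None
    crops: tuple = ("beans", "peas", "lentils", "maize", "sorghum", "millet", "rice")
    crop_epochs: tuple = (2000, 2015)
    #: (crop, epoch, elevation cutoff m): zero the crop above the cutoff there.
    crop_withdrawal: list = field(default_factory=list)
    crop_coverage: float = 0.6          # per-crop fraction of cells cultivated
    duplicate_fraction: float = 0.02
    missing_fraction: float = 0.02
    #: contrast in coupling association the niches are sized to produce
    #: between the wet-hot and dry-cool extremes of the species set.
    planted_coupling_margin_pct: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.env_trends, dict):
            self.env_trends = EnvTrends(**self.env_trends)
        self.species_niches = {
            k: (SpeciesNiche(**v) if isinstance(v, dict) else v)
            for k, v in self.species_niches.items()
        }
        self.validate()

    def validate(self) -> None:
        if self.end_year < self.start_year:
            raise ConfigError("end_year must be >= start_year")
        if self.grid_nx < 2 or self.grid_ny < 2:
            raise ConfigError("grid must be at least 2x2")
        if not (self.lon_max > self.lon_min and self.lat_max > self.lat_min):
            raise ConfigError("lon/lat bounds must be increasing")
        for fname in ("lon_min", "lon_max", "lat_min", "lat_max",
                      "duplicate_fraction", "missing_fraction", "crop_coverage"):
            if not np.isfinite(getattr(self, fname)):
                raise ConfigError(f"non-finite config value for {fname}")
        for fname, v in asdict(self.env_trends).items():
            if not np.isfinite(v):
                raise ConfigError(f"non-finite config value for env_trends.{fname}")
        for sp, niche in self.species_niches.items():
            for fname, v in asdict(niche).items():
                if not np.isfinite(v):
                    raise ConfigError(f"non-finite config value for {sp}.{fname}")
            if niche.lst_sd <= 0 or niche.rzsm_sd <= 0 or niche.elev_sd_m <= 0:
                raise ConfigError(f"all SDs must be > 0 for species {sp}")
            if niche.n_occurrences <= 0:
                raise ConfigError(f"n_occurrences must be > 0 for species {sp}")
        if self.designated_cells is not None:
            for iy, ix in self.designated_cells:
                if not (0 <= iy < self.grid_ny and 0 <= ix < self.grid_nx):
                    raise ConfigError(f"designated cell {(iy, ix)} outside grid")
        for crop, epoch, cutoff in self.crop_withdrawal:
            if crop not in self.crops:
                raise ConfigError(f"withdrawal names unknown crop {crop!r}")
            if epoch not in self.crop_epochs:
                raise ConfigError(f"withdrawal names unknown epoch {epoch!r}")
            if not np.isfinite(cutoff):
                raise ConfigError("withdrawal cutoff must be finite")

    # -- plumbing ------------------------------------------------------
    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def n_months(self) -> int:
        return 12 * self.n_years

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        dx = (self.lon_max - self.lon_min) / self.grid_nx
        dy = (self.lat_max - self.lat_min) / self.grid_ny
        lon = self.lon_min + dx * (np.arange(self.grid_nx) + 0.5)
        lat = self.lat_min + dy * (np.arange(self.grid_ny) + 0.5)
        return lon, lat

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["crops"] = list(d["crops"])
        d["crop_epochs"] = list(d["crop_epochs"])
        d["crop_withdrawal"] = [list(w) for w in d["crop_withdrawal"]]
        if d["designated_cells"] is not None:
            d["designated_cells"] = [list(c) for c in d["designated_cells"]]
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "ScenarioConfig":
        text = path_or_text
        try:
            with open(path_or_text) as fh:
                text = fh.read()
        except (OSError, TypeError):
            pass
        d = yaml.safe_load(text)
        if d.get("crop_withdrawal"):
            d["crop_withdrawal"] = [tuple(w) for w in d["crop_withdrawal"]]
        if d.get("designated_cells"):
            d["designated_cells"] = [tuple(c) for c in d["designated_cells"]]
        for key in ("crops", "crop_epochs"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def default_scenario(seed: int = 0) -> ScenarioConfig:
    """The bundled study scenario: eight species with contrasting niches.

    Witchweed-like species sit in hot, wet, partly montane niches (the
    range-shifting one drifts +25 m/yr); broomrape-like species sit in
    cooler, drier niches, one of them montane with a declining trend.
    Sample sizes (200-400 per species) and the 2006-2022 span follow the
    shape of the occurrence analyses the pipeline targets.
    """
    niches = {
        "Striga hermonthica": SpeciesNiche(30.0, 2.0, 75.0, 10.0, 300.0, 250.0, 300),
        "Striga gesnerioides": SpeciesNiche(30.0, 2.0, 70.0, 10.0, 700.0, 300.0, 300,
                                            elev_trend_per_year=10.0),
        "Striga asiatica": SpeciesNiche(27.0, 3.0, 68.0, 12.0, 900.0, 250.0, 400,
                                        elev_trend_per_year=25.0),
        "Orobanche crenata": SpeciesNiche(22.0, 3.0, 40.0, 12.0, 800.0, 350.0, 300,
                                          elev_trend_per_year=-10.0),
        "Orobanche cumana": SpeciesNiche(26.0, 3.0, 35.0, 12.0, 300.0, 300.0, 250),
        "Orobanche minor": SpeciesNiche(21.0, 3.0, 35.0, 12.0, 400.0, 350.0, 250),
        "Phelipanche aegyptiaca": SpeciesNiche(29.0, 2.0, 25.0, 10.0, 200.0, 250.0, 200),
        "Phelipanche ramosa": SpeciesNiche(23.0, 3.0, 50.0, 12.0, 250.0, 250.0, 250),
    }
    return ScenarioConfig(
        species_niches=niches,
        crop_withdrawal=[("beans", 2015, 1000.0), ("peas", 2015, 1000.0),
                         ("lentils", 2015, 1000.0)],
        seed=seed,
    )


# ----------------------------------------------------------------------
# Environmental grids
# ----------------------------------------------------------------------

def _elevation_surface(config: ScenarioConfig) -> np.ndarray:
    """Smooth surface: gentle west-east rise plus one montane massif.

    The massif peaks near fractional position (0.5, 0.65) at roughly
    1700 m, giving a contiguous designated high-elevation (>1000 m)
    region of a few dozen cells on the default grid.  It sits at
    mid-longitude so the static west-east wetness gradient contributes
    no baseline elevation-moisture correlation: any such correlation is
    built only by the planted moisture trend at designated cells.
    """
    xf = (np.arange(config.grid_nx) + 0.5) / config.grid_nx
    yf = (np.arange(config.grid_ny) + 0.5) / config.grid_ny
    X, Y = np.meshgrid(xf, yf)
    hill = 1500.0 * np.exp(-(((X - 0.5) ** 2) + ((Y - 0.65) ** 2)) / (2 * 0.03))
    return 80.0 + 250.0 * X + hill


def _designated_mask(config: ScenarioConfig, elev: np.ndarray) -> np.ndarray:
    mask = np.zeros(elev.shape, dtype=bool)
    if config.designated_cells is None:
        mask[elev > 1000.0] = True
    else:
        for iy, ix in config.designated_cells:
            mask[iy, ix] = True
    return mask


def generate_env_grids(config: ScenarioConfig) -> dict:
    """Generate {'lst', 'rzsm', 'elev'} grids with the planted structure.

    The LST cell series is baseline - lapse_rate * (elev/1000) + an
    annual sinusoid (phase flipped in the southern hemisphere) + the
    planted linear trend at designated cells + Gaussian noise.  RZSM is
    percentile-like with a longitudinal wetness gradient, the planted
    trend at designated cells, and noise, clipped to [0, 100].
    Identical seed implies bit-identical output.
    """
    rng = config.rng("env")
    env = config.env_trends
    lon, lat = config.axes()
    ny, nx, T = config.grid_ny, config.grid_nx, config.n_months

    elev = _elevation_surface(config)
    designated = _designated_mask(config, elev)

    t = np.arange(T)
    years_elapsed = t / 12.0
    cal = t % 12
    # annual cycle peaking in July north of the equator, January south
    season = np.cos(2 * np.pi * (cal - 6) / 12.0)
    hemis = np.where(lat < 0, -1.0, 1.0)[None, :, None]
    seasonal = env.seasonal_amplitude_c * season[:, None, None] * hemis

    base = env.lst_base_c - env.lapse_rate_c_per_km * (elev / 1000.0)
    trend = env.lst_trend_c_per_year * years_elapsed[:, None, None] * designated[None]
    lst_vals = (base[None] + seasonal + trend
                + rng.normal(0.0, env.noise_sd, size=(T, ny, nx)))

    xf = (np.arange(nx) + 0.5) / nx
    rz_base = env.rzsm_base_pct + env.rzsm_lon_gradient_pct * (2 * xf - 1.0)[None, :]
    rz_trend = env.rzsm_trend_pct_per_year * years_elapsed[:, None, None] * designated[None]
    rz_vals = (rz_base[None] + rz_trend
               + rng.normal(0.0, env.rzsm_noise_sd, size=(T, ny, nx)))
    rz_vals = np.clip(rz_vals, 0.0, 100.0)

    start = (config.start_year, 1)
    return {
        "lst": MonthlyGrid("LST_C", lon, lat, lst_vals, start=start),
        "rzsm": MonthlyGrid("RZSM_PCT", lon, lat, rz_vals, start=start),
        "elev": MonthlyGrid("ELEV_M", lon, lat, elev),
    }


# ----------------------------------------------------------------------
# Occurrences
# ----------------------------------------------------------------------

def generate_occurrences(config: ScenarioConfig, grids: dict) -> pd.DataFrame:
    """Importance-sample occurrence records from the generated world.

    Candidate (cell, month) pairs — months from the second onward, so a
    lag-1 environment exists — are weighted by the product of Gaussian
    niche densities in lag-1 LST, lag-1 RZSM and elevation; the
    preferred elevation drifts by ``elev_trend_per_year``.  Coordinates
    are jittered uniformly inside the cell so nearest-cell extraction
    maps each record back to its generating cell.  A configurable
    fraction of rows is emitted with missing coordinates or as exact
    duplicates to exercise cleaning.  Raises when a species' niche is
    incompatible with the grids (all weights vanish), naming it.
    """
    rng = config.rng("occurrences")
    lst, rzsm, elev = grids["lst"], grids["rzsm"], grids["elev"]
    lon, lat = lst.lon, lst.lat
    ny, nx, T = lat.size, lon.size, lst.n_times
    dx, dy = lon[1] - lon[0], lat[1] - lat[0]

    # flatten candidates: months 1..T-1 (lag-1 exists) x all cells
    tt = np.arange(1, T)
    lag1_lst = lst.values[tt - 1].reshape(tt.size, -1)       # (T-1, cells)
    lag1_rz = rzsm.values[tt - 1].reshape(tt.size, -1)
    elev_flat = elev.values.reshape(-1)
    years = config.start_year + tt // 12
    months = tt % 12 + 1

    frames = []
    rid = 0
    for species in sorted(config.species_niches):
        niche = config.species_niches[species]
        pref = (niche.elev_pref_m
                + niche.elev_trend_per_year * (years - config.start_year))
        logw = (
            -0.5 * ((lag1_lst - niche.lst_mean) / niche.lst_sd) ** 2
            - 0.5 * ((lag1_rz - niche.rzsm_mean) / niche.rzsm_sd) ** 2
            - 0.5 * ((elev_flat[None, :] - pref[:, None]) / niche.elev_sd_m) ** 2
        )
        logw[~np.isfinite(logw)] = -np.inf
        m = logw.max()
        # density underflows to zero at every candidate -> no support
        if not np.isfinite(m) or m < -745.0:
            raise ConfigError(f"niche of species {species!r} is incompatible "
                              "with the generated grids (empty candidate set)")
        w = np.exp(logw - m).ravel()
        total = w.sum()
        if total <= 0:
            raise ConfigError(f"niche of species {species!r} is incompatible "
                              "with the generated grids (empty candidate set)")
        pick = rng.choice(w.size, size=niche.n_occurrences, replace=True,
                          p=w / total)
        ti, ci = np.unravel_index(pick, logw.shape)
        iy, ix = np.unravel_index(ci, (ny, nx))
        jx = rng.uniform(-0.499, 0.499, size=pick.size)
        jy = rng.uniform(-0.499, 0.499, size=pick.size)
        frames.append(pd.DataFrame({
            "species": species,
            "decimalLongitude": lon[ix] + jx * dx,
            "decimalLatitude": lat[iy] + jy * dy,
            "year": years[ti],
            "month": months[ti],
        }))
        rid += niche.n_occurrences
    table = pd.concat(frames, ignore_index=True)

    # planted defects: duplicates first, then missing coordinates
    n = len(table)
    n_dup = int(round(config.duplicate_fraction * n))
    if n_dup:
        dup_rows = table.iloc[rng.choice(n, size=n_dup, replace=False)]
        table = pd.concat([table, dup_rows], ignore_index=True)
    n_miss = int(round(config.missing_fraction * n))
    if n_miss:
        idx = rng.choice(len(table), size=n_miss, replace=False)
        col = np.where(rng.random(n_miss) < 0.5,
                       "decimalLongitude", "decimalLatitude")
        for i, c in zip(idx, col):
            table.loc[i, c] = np.nan

    order = rng.permutation(len(table))
    table = table.iloc[order].reset_index(drop=True)
    table.insert(0, "record_id", [f"syn{i:06d}" for i in range(len(table))])
    return table


# ----------------------------------------------------------------------
# Crop grids
# ----------------------------------------------------------------------

def generate_crop_grids(config: ScenarioConfig, elev: MonthlyGrid) -> dict:
    """Two-epoch harvested-area layers, {epoch: {crop: static grid}}.

    A shared baseline layer per crop (random cultivated cells at
    ``crop_coverage`` density with uniform positive areas) is copied to
    both epochs; ``crop_withdrawal`` entries then zero the named crop
    above the elevation cutoff in the named epoch only, so with no
    withdrawal entries the epochs are identical.
    """
    rng = config.rng("crops")
    lon, lat = elev.lon, elev.lat
    shape = (lat.size, lon.size)
    baseline = {}
    for crop in config.crops:
        cultivated = rng.random(shape) < config.crop_coverage
        area = rng.uniform(0.05, 0.5, size=shape)
        baseline[crop] = np.where(cultivated, area, 0.0)

    out = {}
    for epoch in config.crop_epochs:
        layers = {}
        for crop in config.crops:
            vals = baseline[crop].copy()
            for wcrop, wepoch, cutoff in config.crop_withdrawal:
                if wcrop == crop and wepoch == epoch:
                    vals[elev.values > cutoff] = 0.0
            layers[crop] = MonthlyGrid("CROP_AREA", lon, lat, vals,
                                       attrs={"crop": crop, "epoch": epoch})
        out[epoch] = layers
    return out
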