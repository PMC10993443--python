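"""Synthetic two-wave child-anthropometry surveys with matching rasters.

The real inputs of this kind of analysis — national household-survey child
records with GPS-located clusters plus gridded biophysical attribute maps —
are access-restricted.  This module generates fixtures with the statistical
structure the downstream stages assume, so the whole pipeline is testable
and every estimate can be checked against known generating values.

What is emulated
----------------
* two survey waves ("2009" baseline, "2016" endline), several thousand
  children each, spread over districts that tile a rectangular extent;
* HAZ/WAZ/WHZ outcomes from a linear covariate model with additive district
  effects and Gaussian noise at realistic SDs (defaults 1.95 / 1.25 / 1.61
  Z-score units);
* joint missingness of the three Z-scores, completely at random, at
  per-wave rates (defaults 24.8% baseline, 29.6% endline);
* a district-level intervention: "JP" districts carry a baseline offset
  (unequal starting conditions) and an additive endline-wave program effect
  per outcome (defaults +0.37 WHZ, −0.20 HAZ, +0.12 WAZ) — the ground truth
  the impact stage should recover;
* one 30-arcsecond raster per biophysical attribute, piecewise-constant by
  district with smooth low-amplitude within-district variation.

Districts are axis-aligned rectangles tiling the extent, so the
point-in-district test is trivially invertible for oracle checks.  A single
seed feeds three independent sub-streams (landscape / records /
missingness) so each part regenerates independently and deterministically.

Covariate marginals are not dictated by any survey: binary covariates are
Bernoulli (default prevalence 0.5), categorical ones uniform over their
levels, continuous ones Normal — all configurable.  That is the simplest
structure that exercises every screening branch; it does not attempt
realistic inter-covariate correlation or spatial autocorrelation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import RasterGrid, write_geotiff, read_geotiff

#: Administrative districts of Timor-Leste (alphabetical); index = district id.
DISTRICT_NAMES = [
    "Aileu", "Ainaro", "Baucau", "Bobonaro", "Cova Lima", "Dili", "Ermera",
    "Lautem", "Liquica", "Manatuto", "Manufahi", "Oecusse", "Viqueque",
]

#: Districts that received the joint program: Aileu, Baucau, Manatuto, Oecusse.
DEFAULT_JP_IDS = frozenset({0, 2, 9, 11})

RASTER_ATTRIBUTES = (
    "mvhi", "altitude", "slope", "soil_class", "population_density",
    "crop_cover",
)

#: Uniform ranges the per-district base value of each attribute is drawn from.
_ATTRIBUTE_RANGES = {
    "mvhi": (20.0, 60.0),               # vegetation-health index
    "altitude": (100.0, 1500.0),        # m
    "slope": (2.0, 35.0),               # %
    "population_density": (10.0, 600.0),  # persons / km^2
    "crop_cover": (5.0, 80.0),          # %
}

#: Attributes held piecewise-constant (class codes get no smooth variation).
_INTEGER_ATTRIBUTES = {"soil_class"}

DEFAULT_COEF_TABLE = {
    # Z-score units per unit / per level vs reference
    "haz": {
        "intercept": -1.29,
        "female": 0.35,
        "hungry_season": 0.28,
        "age_years[1]": -1.03, "age_years[2]": -0.77,
        "age_years[3]": -1.02, "age_years[4]": -0.83,
    },
    "waz": {
        "intercept": -1.31,
        "female": 0.11,
        "age_years[1]": -0.82, "age_years[2]": -1.04,
        "age_years[3]": -1.14, "age_years[4]": -1.22,
        "bmi_class[normal]": 0.33, "bmi_class[overweight]": 0.47,
        "wealth[poorer]": 0.08, "wealth[richer]": 0.14,
        "wealth[richest]": 0.23,
    },
    "whz": {
        "intercept": -1.54,
        "hungry_season": -0.13,
        "age_years[1]": -0.64, "age_years[2]": -0.74,
        "age_years[3]": -0.62, "age_years[4]": -0.90,
        "bmi_class[normal]": 0.29, "bmi_class[overweight]": 0.45,
    },
}

DEFAULT_NOISE_SD = {"haz": 1.95, "waz": 1.25, "whz": 1.61}
DEFAULT_MISSING_FRAC = {"2009": 0.248, "2016": 0.296}
DEFAULT_JP_WAVE2_EFFECT = {"haz": -0.20, "waz": 0.12, "whz": 0.37}
DEFAULT_JP_BASELINE_SHIFT = {"haz": 0.78, "waz": 0.0, "whz": -0.66}

OUTCOMES = ("haz", "waz", "whz")
WAVES = ("2009", "2016")


@dataclass
class GenConfig:
    """Everything needed to regenerate a synthetic bundle."""

    n_children_per_wave: int = 5000
    n_districts: int = 13
    jp_district_ids: frozenset = DEFAULT_JP_IDS
    coef_table: dict = field(default_factory=lambda: {
        o: dict(v) for o, v in DEFAULT_COEF_TABLE.items()})
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    missing_frac: dict = field(default_factory=lambda: dict(DEFAULT_MISSING_FRAC))
    seed: int = 0
    # (lat_min, lat_max, lon_min, lon_max), decimal degrees
    raster_extent: tuple = (-9.5, -8.1, 124.0, 127.3)
    resolution_arcsec: float = 30.0
    # intervention truth
    jp_wave2_effect: dict = field(default_factory=lambda: dict(DEFAULT_JP_WAVE2_EFFECT))
    jp_baseline_shift: dict = field(default_factory=lambda: dict(DEFAULT_JP_BASELINE_SHIFT))
    district_effect_sd: float = 0.30
    # covariate marginals
    binary_covariates: dict = field(default_factory=lambda: {
        "female": 0.5, "hungry_season": 0.5})
    categorical_covariates: dict = field(default_factory=lambda: {
        "age_years": ["0", "1", "2", "3", "4"],
        "bmi_class": ["underweight", "normal", "overweight"],
        "wealth": ["poorest", "poorer", "middle", "richer", "richest"],
    })
    continuous_covariates: dict = field(default_factory=dict)  # name -> (mean, sd)
    n_noise_covariates: int = 3          # pure-noise Bernoulli(0.5) columns
    # landscape overrides
    attribute_district_values: dict = field(default_factory=dict)
    smooth_frac: float = 0.02            # within-district variation amplitude

    def __post_init__(self) -> None:
        self.jp_district_ids = frozenset(int(i) for i in self.jp_district_ids)
        if self.n_children_per_wave <= 0 or self.n_districts <= 0:
            raise ValueError("sample and district counts must be positive")
        if not self.jp_district_ids <= set(range(self.n_districts)):
            raise ValueError("jp_district_ids must be a subset of district ids")
        if any(sd <= 0 for sd in self.noise_sd.values()):
            raise ValueError("noise SDs must be positive")
        for wave, frac in self.missing_frac.items():
            if not 0 <= frac < 1:
                raise ValueError(f"missing_frac[{wave}] must be in [0, 1)")
        lat_min, lat_max, lon_min, lon_max = self.raster_extent
        if not (lat_max > lat_min and lon_max > lon_min):
            raise ValueError("degenerate raster extent (zero width or height)")
        if self.resolution_arcsec <= 0:
            raise ValueError("resolution must be positive")

    @property
    def resolution_deg(self) -> float:
        return self.resolution_arcsec / 3600.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["jp_district_ids"] = sorted(self.jp_district_ids)
        d["raster_extent"] = list(self.raster_extent)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GenConfig":
        d = dict(d)
        d["jp_district_ids"] = frozenset(d.get("jp_district_ids", DEFAULT_JP_IDS))
        d["raster_extent"] = tuple(d.get("raster_extent", (-9.5, -8.1, 124.0, 127.3)))
        return cls(**d)


@dataclass
class SyntheticBundle:
    records: pd.DataFrame
    rasters: dict
    truth: dict


def _streams(seed: int):
    """Split one seed into landscape / records / missingness generators."""
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(s) for s in children)


def district_regions(n_districts: int, extent) -> list:
    """Axis-aligned rectangles tiling the extent, one per district.

    Districts are laid out on a near-square row grid; row i holds its even
    share of districts as equal-width columns.  Returns
    ``[(lat_min, lat_max, lon_min, lon_max), ...]`` indexed by district id.
    """
    lat_min, lat_max, lon_min, lon_max = extent
    n_rows = max(int(np.floor(np.sqrt(n_districts))), 1)
    base, extra = divmod(n_districts, n_rows)
    counts = [base + (1 if r < extra else 0) for r in range(n_rows)]
    lat_edges = np.linspace(lat_min, lat_max, n_rows + 1)
    regions = []
    for r, cnt in enumerate(counts):
        lon_edges = np.linspace(lon_min, lon_max, cnt + 1)
        for c in range(cnt):
            regions.append((
                float(lat_edges[r]), float(lat_edges[r + 1]),
                float(lon_edges[c]), float(lon_edges[c + 1]),
            ))
    return regions


def district_of_points(lats, lons, regions) -> np.ndarray:
    """Invert the rectangle tiling: district id per point (−1 if outside)."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    out = np.full(len(lats), -1, dtype=int)
    for d, (a0, a1, o0, o1) in enumerate(regions):
        inside = (lats >= a0) & (lats <= a1) & (lons >= o0) & (lons <= o1)
        out[inside & (out == -1)] = d
    return out


def generate_landscape(cfg: GenConfig, rng: np.random.Generator | None = None) -> dict:
    """One :class:`RasterGrid` per biophysical attribute.

    Values are piecewise-constant by district region with a smooth
    low-amplitude sinusoidal variation inside each district (class-code
    attributes stay exactly constant per district).  Deterministic given the
    config seed.
    """
    rng = rng if rng is not None else _streams(cfg.seed)[0]
    lat_min, lat_max, lon_min, lon_max = cfg.raster_extent
    res = cfg.resolution_deg
    n_rows = max(int(np.ceil((lat_max - lat_min) / res)), 1)
    n_cols = max(int(np.ceil((lon_max - lon_min) / res)), 1)
    regions = district_regions(cfg.n_districts, cfg.raster_extent)
    lats = lat_max - (np.arange(n_rows) + 0.5) * res
    lons = lon_min + (np.arange(n_cols) + 0.5) * res
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    district = district_of_points(glat.ravel(), glon.ravel(), regions)
    district = district.reshape(glat.shape)
    # cell centers just past the stated extent (ceil overshoot) → nearest district
    district[district == -1] = 0

    rasters = {}
    for attr in RASTER_ATTRIBUTES:
        if attr in cfg.attribute_district_values:
            bases = np.asarray(cfg.attribute_district_values[attr], dtype=float)
            if len(bases) != cfg.n_districts:
                raise ValueError(
                    f"attribute_district_values[{attr!r}] needs one value "
                    f"per district"
                )
        elif attr == "soil_class":
            bases = rng.integers(1, 5, size=cfg.n_districts).astype(float)
        else:
            lo, hi = _ATTRIBUTE_RANGES[attr]
            bases = rng.uniform(lo, hi, size=cfg.n_districts)
        values = bases[district]
        if attr not in _INTEGER_ATTRIBUTES and cfg.smooth_frac > 0:
            phase = rng.uniform(0, 2 * np.pi)
            values = values * (
                1.0
                + cfg.smooth_frac
                * np.sin(4 * np.pi * (glat - lat_min) / (lat_max - lat_min) + phase)
                * np.sin(4 * np.pi * (glon - lon_min) / (lon_max - lon_min))
            )
        rasters[attr] = RasterGrid(
            values=values,
            origin_lat=lat_max,
            origin_lon=lon_min,
            resolution=res,
            attribute_name=attr,
        )
    return rasters


def _effect_value(df: pd.DataFrame, rasters: dict, effect: str) -> np.ndarray:
    """Numeric design column for one effect name ("var" or "var[level]")."""
    if "[" in effect:
        var, level = effect[:-1].split("[", 1)
        if var not in df.columns:
            raise KeyError(f"effect {effect!r} references unknown covariate {var!r}")
        return (df[var].astype(str) == level).to_numpy(dtype=float)
    if effect in df.columns:
        return df[effect].to_numpy(dtype=float)
    if effect in rasters:
        grid = rasters[effect]
        vals = np.empty(len(df))
        for k, (lat, lon) in enumerate(zip(df["lat"], df["lon"])):
            i, j = grid.cell_index(lat, lon)
            i = min(max(i, 0), grid.shape[0] - 1)
            j = min(max(j, 0), grid.shape[1] - 1)
            vals[k] = grid.values[i, j]
        return vals
    raise KeyError(f"effect {effect!r} matches no covariate or raster attribute")


def generate_records(
    cfg: GenConfig, rasters: dict, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict]:
    """Two waves of child records with outcomes from the generating model.

    Returns ``(records, truth)`` where ``truth`` holds the realized district
    effects and everything needed to recompute expected outcome means
    analytically.  Z-scores here are complete; missingness is injected
    separately so both versions are available.
    """
    if not any(cfg.coef_table.get(o) for o in OUTCOMES):
        raise ValueError("coef_table is empty; the generating model is undefined")
    rng = rng if rng is not None else _streams(cfg.seed)[1]
    regions = district_regions(cfg.n_districts, cfg.raster_extent)
    n = cfg.n_children_per_wave
    total = 2 * n

    district = rng.integers(0, cfg.n_districts, size=total)
    lat = np.empty(total)
    lon = np.empty(total)
    for d, (a0, a1, o0, o1) in enumerate(regions):
        m = district == d
        k = int(m.sum())
        lat[m] = rng.uniform(a0, a1, size=k)
        lon[m] = rng.uniform(o0, o1, size=k)

    df = pd.DataFrame({
        "wave": np.repeat(list(WAVES), n),
        "district_id": district,
        "district": [DISTRICT_NAMES[d] if d < len(DISTRICT_NAMES) else f"D{d}"
                     for d in district],
        "lat": lat,
        "lon": lon,
    })
    for name, prev in cfg.binary_covariates.items():
        df[name] = rng.binomial(1, prev, size=total)
    for name, levels in cfg.categorical_covariates.items():
        df[name] = rng.choice(levels, size=total)
    for name, (mu, sd) in cfg.continuous_covariates.items():
        df[name] = rng.normal(mu, sd, size=total)
    for k in range(cfg.n_noise_covariates):
        df[f"noise{k + 1}"] = rng.binomial(1, 0.5, size=total)

    jp = np.isin(district, list(cfg.jp_district_ids))
    df["jp"] = jp
    wave2 = (df["wave"] == WAVES[1]).to_numpy()

    district_effects = {
        o: rng.normal(0.0, cfg.district_effect_sd, size=cfg.n_districts)
        for o in OUTCOMES
    }
    for o in OUTCOMES:
        coefs = dict(cfg.coef_table.get(o, {}))
        y = np.full(total, float(coefs.pop("intercept", 0.0)))
        for effect, beta in coefs.items():
            y += beta * _effect_value(df, rasters, effect)
        y += district_effects[o][district]
        y += np.where(jp, cfg.jp_baseline_shift.get(o, 0.0), 0.0)
        y += np.where(jp & wave2, cfg.jp_wave2_effect.get(o, 0.0), 0.0)
        y += rng.normal(0.0, cfg.noise_sd[o], size=total)
        df[o] = y

    truth = {
        "config": cfg.to_dict(),
        "district_regions": [list(r) for r in regions],
        "district_effects": {o: v.tolist() for o, v in district_effects.items()},
        "jp_district_ids": sorted(cfg.jp_district_ids),
    }
    return df, truth


def inject_missingness(
    records: pd.DataFrame, cfg: GenConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Mask the three Z-scores jointly, completely at random, per wave.

    A record is either fully observed or has all three Z-scores missing —
    never a partial mask.  The list length is preserved.
    """
    rng = rng if rng is not None else _streams(cfg.seed)[2]
    out = records.copy()
    mask = np.zeros(len(out), dtype=bool)
    for wave, frac in cfg.missing_frac.items():
        in_wave = (out["wave"].astype(str) == str(wave)).to_numpy()
        mask |= in_wave & (rng.random(len(out)) < frac)
    out.loc[mask, list(OUTCOMES)] = np.nan
    return out


def generate_bundle(cfg: GenConfig) -> SyntheticBundle:
    """Landscape + records + missingness from one seed, deterministically."""
    rng_land, rng_rec, rng_miss = _streams(cfg.seed)
    rasters = generate_landscape(cfg, rng_land)
    complete, truth = generate_records(cfg, rasters, rng_rec)
    records = inject_missingness(complete, cfg, rng_miss)
    truth["complete_outcomes"] = "available pre-masking; regenerate with the seed"
    return SyntheticBundle(records=records, rasters=rasters, truth=truth)


def write_fixture(bundle: SyntheticBundle, directory) -> dict:
    """Records as CSV, rasters as GeoTIFF, truth as JSON; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    rec_path = directory / "records.csv"
    bundle.records.to_csv(rec_path, index=False)
    paths["records"] = str(rec_path)
    for name, grid in bundle.rasters.items():
        p = directory / f"{name}.tif"
        write_geotiff(grid, p)
        paths[f"raster:{name}"] = str(p)
    truth_path = directory / "truth.json"
    truth_path.write_text(json.dumps(bundle.truth, indent=2))
    paths["truth"] = str(truth_path)
    return paths


def read_fixture(directory) -> SyntheticBundle:
    """Round-trip reader for :func:`write_fixture` output."""
    directory = Path(directory)
    records = pd.read_csv(directory / "records.csv",
                          dtype={"wave": str}, keep_default_na=True)
    truth = json.loads((directory / "truth.json").read_text())
    rasters = {}
    for p in sorted(directory.glob("*.tif")):
        grid = read_geotiff(p)
        rasters[grid.attribute_name or p.stem] = grid
    return SyntheticBundle(records=records, rasters=rasters, truth=truth)
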