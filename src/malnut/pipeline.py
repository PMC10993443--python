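"""End-to-end orchestration: synth → geolink → anthro → screen → modelsel → impact.

One validated configuration drives a reproducible run: each enabled stage
reads what the previous stages produced, writes its reports under the output
directory, and registers every output file (with a SHA-256 hash) in a run
manifest.  Re-running with the same config and seed produces byte-identical
outputs and an identical manifest; wall-clock timings go to the structured
JSON-lines log only, never into the manifest.

Warnings carry stable codes (``W-SMALL-STRATUM``, ``W-RESAMPLE-FAIL``,
``W-EXCESS-FLOOR``) so tests and downstream tooling can assert on them.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anthro, geolink, impact, modelsel, screen, synthetic

_KNOWN_KEYS = {
    "out_dir", "seed", "stages", "generator", "alpha", "resamples", "fraction",
    "retain", "z_cutoff", "excess_constant", "small_stratum_n", "strata",
    "outcomes", "link_attributes", "records_csv", "raster_dir",
    "screen_covariates", "min_obs_per_effect",
}

_STAGES = ("synth", "geolink", "anthro", "screen", "modelsel", "impact")

#: Reference levels for the built-in variable dictionary.
DEFAULT_REFERENCES = {
    "age_years": "0",
    "bmi_class": "underweight",
    "wealth": "poorest",
    "household_size_cat": "0–5",
    "altitude_cat": "<=800",
    "population_density_cat": "<=50",
    "slope_cat": "8–16",
}

_ID_COLUMNS = {"wave", "district_id", "district", "lat", "lon", "jp",
               "haz", "waz", "whz"}


@dataclass
class RunConfig:
    out_dir: str
    seed: int
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    generator: dict = field(default_factory=dict)
    alpha: float = 0.05
    resamples: int = 100
    fraction: float = 0.75
    retain: float = 0.20
    z_cutoff: float = -2.0
    excess_constant: float = 2.3
    small_stratum_n: int = 50
    strata: list = field(default_factory=lambda: ["female", "bmi_class", "wealth"])
    outcomes: list = field(default_factory=lambda: ["haz", "waz", "whz"])
    link_attributes: list = field(default_factory=lambda: ["mvhi", "altitude"])
    records_csv: str | None = None
    raster_dir: str | None = None
    screen_covariates: list | None = None
    min_obs_per_effect: int = 10


class ConfigError(ValueError):
    pass


def validate(config: dict | str | Path) -> RunConfig:
    """Fill defaults, reject unknown keys and out-of-range values."""
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text()) or {}
    if not isinstance(config, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    if "seed" not in config or config["seed"] is None:
        raise ConfigError("seed is mandatory: every stochastic stage requires it")
    cfg = RunConfig(out_dir=str(config.get("out_dir", "run_out")),
                    seed=int(config["seed"]))
    for key, value in config.items():
        if key in ("out_dir", "seed"):
            continue
        if key == "stages":
            bad = set(value) - set(_STAGES)
            if bad:
                raise ConfigError(f"unknown stages: {sorted(bad)}")
            cfg.stages.update({k: bool(v) for k, v in value.items()})
        else:
            setattr(cfg, key, value)
    if not 0 < cfg.fraction <= 1:
        raise ConfigError("fraction must be in (0, 1]")
    if not 0 <= cfg.retain <= 1:
        raise ConfigError("retain must be in [0, 1]")
    if not 0 < cfg.alpha < 1:
        raise ConfigError("alpha must be in (0, 1)")
    if cfg.resamples < 1:
        raise ConfigError("resamples must be >= 1")
    for path_key in ("records_csv", "raster_dir"):
        p = getattr(cfg, path_key)
        if p is not None and not Path(p).exists():
            raise ConfigError(f"{path_key} does not exist: {p}")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Run:
    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.out = Path(cfg.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest = {"seed": cfg.seed, "config": _config_dict(cfg),
                         "stages": {}}
        self.log_path = self.out / "run_log.jsonl"
        self._log_lines = []
        self.records: pd.DataFrame | None = None
        self.rasters: dict = {}

    def log(self, **entry):
        self._log_lines.append(json.dumps(entry, default=str))

    def register(self, stage: str, *paths, warnings=()):
        rec = self.manifest["stages"].setdefault(
            stage, {"outputs": {}, "warnings": [], "skipped": False})
        for p in paths:
            rec["outputs"][str(Path(p).relative_to(self.out))] = _sha256(Path(p))
        rec["warnings"].extend(warnings)

    def finish(self):
        self.log_path.write_text("\n".join(self._log_lines) + "\n")
        manifest_path = self.out / "manifest.json"
        manifest_path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        return manifest_path


def _config_dict(cfg: RunConfig) -> dict:
    d = {k: getattr(cfg, k) for k in _KNOWN_KEYS if hasattr(cfg, k)}
    d["stages"] = dict(cfg.stages)
    return d


def run(config: RunConfig | dict | str | Path) -> dict:
    """Execute the enabled stages in order; returns the manifest dict."""
    cfg = config if isinstance(config, RunConfig) else validate(config)
    state = _Run(cfg)
    for stage in _STAGES:
        enabled = cfg.stages.get(stage, True)
        t0 = time.perf_counter()
        if not enabled:
            state.manifest["stages"][stage] = {
                "outputs": {}, "warnings": [], "skipped": True}
            state.log(stage=stage, status="skipped")
            continue
        _STAGE_FUNCS[stage](state)
        state.log(stage=stage, status="ok",
                  elapsed_s=round(time.perf_counter() - t0, 3))
    state.finish()
    return state.manifest


# ---------------------------------------------------------------------------
# stages

def _stage_synth(state: _Run):
    cfg = state.cfg
    gen = synthetic.GenConfig(seed=cfg.seed, **cfg.generator)
    bundle = synthetic.generate_bundle(gen)
    paths = synthetic.write_fixture(bundle, state.out / "synth")
    state.records = bundle.records
    state.rasters = bundle.rasters
    state.register("synth", *paths.values())


def _load_inputs(state: _Run):
    cfg = state.cfg
    if state.records is None:
        if cfg.records_csv:
            state.records = pd.read_csv(cfg.records_csv, dtype={"wave": str})
        elif (state.out / "synth" / "records.csv").exists():
            state.records = pd.read_csv(state.out / "synth" / "records.csv",
                                        dtype={"wave": str})
        else:
            raise FileNotFoundError(
                "no records available: enable the synth stage or set records_csv")
    if not state.rasters:
        raster_dir = Path(cfg.raster_dir) if cfg.raster_dir else state.out / "synth"
        if raster_dir.exists():
            for p in sorted(raster_dir.glob("*.tif")):
                grid = synthetic.read_geotiff(p)
                state.rasters[grid.attribute_name or p.stem] = grid


def _stage_geolink(state: _Run):
    cfg = state.cfg
    _load_inputs(state)
    wanted = {k: v for k, v in state.rasters.items() if k in cfg.link_attributes}
    warnings_ = []
    if wanted:
        names = list(wanted)
        reference = wanted[names[0]]
        aligned = {names[0]: reference}
        for name in names[1:]:
            aligned[name] = geolink.resample_to_reference(wanted[name], reference)
        linked, audit = geolink.link_points(state.records, aligned)
    else:
        linked, audit = state.records.copy(), pd.DataFrame()
        warnings_.append("W-NO-RASTERS: no requested attributes found; pass-through")
    analysis_cols = [c for c in linked.columns if not c.endswith("_link_km")]
    dataset = geolink.harmonize(linked, analysis_cols)
    state.records = dataset.records
    out_dir = state.out / "geolink"
    out_dir.mkdir(exist_ok=True)
    linked_path = out_dir / "linked.csv"
    dataset.records.to_csv(linked_path, index=False)
    audit_path = out_dir / "link_audit.csv"
    audit.to_csv(audit_path, index=False)
    (out_dir / "harmonize.json").write_text(json.dumps(
        {"dropped_count": dataset.dropped_count,
         "surviving": len(dataset.records)}, indent=2))
    state.register("geolink", linked_path, audit_path,
                   out_dir / "harmonize.json", warnings=warnings_)


def _stage_anthro(state: _Run):
    _load_inputs(state)
    records = state.records
    waves = sorted(records["wave"].astype(str).unique())
    report = {"waves": {}, "missingness": {}}
    warnings_ = []
    for wave in waves:
        summary = anthro.summarize(records, wave)
        report["waves"][wave] = summary.to_dict()
        for cond, pct in summary.prevalence.items():
            if pct < anthro.NATURAL_PREVALENCE_PCT and pct > 0:
                warnings_.append(
                    f"W-EXCESS-FLOOR: {cond} prevalence in {wave} below the "
                    "2.3% natural background; excess floored at 0")
        try:
            report["missingness"][wave] = anthro.missingness_report(records, wave)
        except ValueError:
            pass
    report["footer"] = (
        "excess prevalence = observed − 2.3 (natural background); report "
        "percentages round half-up; underlying values at full precision"
    )
    out_dir = state.out / "anthro"
    out_dir.mkdir(exist_ok=True)
    path = out_dir / "anthro_summary.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True))
    state.register("anthro", path, warnings=warnings_)


def _infer_covariates(state: _Run) -> list:
    cfg = state.cfg
    if cfg.screen_covariates:
        return list(cfg.screen_covariates)
    skip = _ID_COLUMNS
    return [c for c in state.records.columns
            if c not in skip and not c.endswith("_link_km")]


def _variable_kind(series: pd.Series) -> str:
    vals = series.dropna()
    if vals.dtype == object or isinstance(vals.dtype, pd.CategoricalDtype):
        return "binary" if vals.nunique() == 2 else "categorical"
    if vals.nunique() <= 2:
        return "binary"
    if np.issubdtype(vals.dtype, np.integer) and vals.nunique() <= 10:
        return "categorical"
    return "continuous"


def _stage_screen(state: _Run):
    cfg = state.cfg
    _load_inputs(state)
    baseline = sorted(state.records["wave"].astype(str).unique())[0]
    data = state.records[state.records["wave"].astype(str) == baseline]
    rows = []
    for outcome in cfg.outcomes:
        y = data[outcome].dropna()
        for var in _infer_covariates(state):
            sub = data.dropna(subset=[outcome, var])
            kind = _variable_kind(sub[var])
            row = {"outcome": outcome, "variable": var, "kind": kind}
            try:
                if kind == "binary":
                    r = screen.ttest_dichotomous(
                        sub[outcome].to_numpy(), sub[var].to_numpy(), variable=var)
                    row.update(test="ttest", statistic=r.t, p=r.p,
                               diff_means=r.diff_means, branch=r.branch,
                               significant=r.p < cfg.alpha)
                elif kind == "categorical":
                    r = screen.anova_categorical(
                        sub[outcome].to_numpy(), sub[var].to_numpy(), variable=var)
                    row.update(test="anova", statistic=r.F, p=r.p,
                               r_square=r.r_square,
                               lowest_mean_level=str(r.lowest_mean_level),
                               significant=r.p < cfg.alpha)
                else:
                    # categorical version screened first; continuous original
                    # only enters if the categorical shows nothing
                    cat = screen.categorize(sub[var], "quartiles")
                    ra = screen.anova_categorical(
                        sub[outcome].to_numpy(), np.asarray(cat), variable=var)
                    if ra.p < cfg.alpha:
                        row.update(test="anova(categorized)", statistic=ra.F,
                                   p=ra.p, r_square=ra.r_square,
                                   significant=True)
                    else:
                        method = screen.choose_method(sub[var], sub[outcome])
                        rc = screen.correlate(sub[var], sub[outcome], method,
                                              variable=var)
                        row.update(test=f"correlation({method})", statistic=rc.r,
                                   p=rc.p, ci_low=rc.ci95[0], ci_high=rc.ci95[1],
                                   significant=rc.reportable)
            except ValueError as exc:
                row.update(test="failed", error=str(exc), significant=False)
            rows.append(row)
    report = pd.DataFrame(rows)
    out_dir = state.out / "screen"
    out_dir.mkdir(exist_ok=True)
    csv_path = out_dir / "screen_report.csv"
    report.to_csv(csv_path, index=False)
    json_path = out_dir / "screen_report.json"
    json_path.write_text(json.dumps({
        "header": "bivariate screen; NO multiple-testing correction applied",
        "baseline_wave": baseline,
        "alpha": cfg.alpha,
        "results": rows,
    }, indent=2, sort_keys=True, default=float))
    state.screen_report = report
    state.register("screen", csv_path, json_path)


def _stage_modelsel(state: _Run):
    cfg = state.cfg
    _load_inputs(state)
    baseline = sorted(state.records["wave"].astype(str).unique())[0]
    data = state.records[state.records["wave"].astype(str) == baseline]
    screen_report = getattr(state, "screen_report", None)
    out = {}
    warnings_ = []
    for outcome in cfg.outcomes:
        continuous, categorical = [], {}
        for var in _infer_covariates(state):
            kind = _variable_kind(data[var].dropna())
            if screen_report is not None:
                sig = screen_report[(screen_report["outcome"] == outcome)
                                    & (screen_report["variable"] == var)]
                if len(sig) and not bool(sig.iloc[0].get("significant", False)):
                    continue
            if kind in ("binary", "continuous"):
                continuous.append(var)
            else:
                levels = sorted(data[var].dropna().astype(str).unique())
                ref = DEFAULT_REFERENCES.get(var, levels[0])
                categorical[var] = ref
        spec = modelsel.ModelSpec(
            outcome=outcome, continuous=continuous, categorical=categorical,
            alpha_stay=cfg.alpha, min_obs_per_effect=cfg.min_obs_per_effect)
        if not continuous and not categorical:
            out[outcome] = {"note": "no screened candidates"}
            continue
        main = modelsel.backward_select(data, spec)
        stability = modelsel.stability_select(
            data, spec, n_resamples=cfg.resamples, fraction=cfg.fraction,
            retain=cfg.retain, seed=cfg.seed)
        if stability.n_failed:
            warnings_.append(
                f"W-RESAMPLE-FAIL: {stability.n_failed} resample fits failed "
                f"for {outcome}")
        comparison = modelsel.compare_models(main, stability)
        out[outcome] = {
            "main": {
                "effects": main.effects,
                "coefficients": main.coefficients,
                "pvalues": main.pvalues,
                "intercept": main.intercept,
                "adjusted_r_square": main.adjusted_r_square,
                "n": main.n,
            },
            "stability": {
                "selection_frequency": stability.selection_frequency,
                "averaged_coefficients": stability.averaged_coefficients,
                "retained": stability.retained,
                "n_resamples": stability.n_resamples,
                "n_failed": stability.n_failed,
            },
            "comparison": comparison,
        }
    out_dir = state.out / "modelsel"
    out_dir.mkdir(exist_ok=True)
    path = out_dir / "models.json"
    path.write_text(json.dumps(out, indent=2, sort_keys=True, default=float))
    state.register("modelsel", path, warnings=warnings_)


def _stage_impact(state: _Run):
    cfg = state.cfg
    _load_inputs(state)
    records = state.records
    if "jp" not in records.columns:
        raise KeyError("records need a 'jp' exposure column (district membership)")
    out_dir = state.out / "impact"
    out_dir.mkdir(exist_ok=True)
    warnings_ = []
    frames = []
    texts = []
    strata = [s for s in cfg.strata if s in records.columns]
    for outcome in cfg.outcomes:
        rows = impact.impact_table(records, outcome, strata)
        n_small = sum(1 for r in rows if not r.reliable)
        if n_small:
            warnings_.append(
                f"W-SMALL-STRATUM: {n_small} {outcome} strata below "
                f"{impact.SMALL_STRATUM_N} children")
        frames.append(impact.table_to_frame(rows))
        texts.append(f"== {outcome.upper()} ==\n" + impact.format_table(rows))
    machine = pd.concat(frames, ignore_index=True)
    csv_path = out_dir / "impact.csv"
    machine.to_csv(csv_path, index=False)
    txt_path = out_dir / "impact.txt"
    txt_path.write_text(
        "\n\n".join(texts)
        + "\n\nimpact = JP change − non-JP change; computed values reported "
        "at full precision in impact.csv\n")
    state.register("impact", csv_path, txt_path, warnings=warnings_)


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "geolink": _stage_geolink,
    "anthro": _stage_anthro,
    "screen": _stage_screen,
    "modelsel": _stage_modelsel,
    "impact": _stage_impact,
}
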