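"""End-to-end orchestration: simulate -> niche shift -> clone filter ->
phenotype statistics -> darwin rates.

One global seed drives every stage; each stochastic stage gets a child
seed derived from ``numpy.random.SeedSequence(global_seed, stage_index)``
so stages are individually reproducible. Every run writes a manifest
with the configuration, the seed and SHA-256 checksums of each output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import env_niche, ordinal, popgen, rates
from .rasters import write_env_dir
from .synthetic_world import (GenoSimParams, PhenoSimParams, WorldConfig,
                              make_genotypes, make_phenotypes, make_world)

STAGES = ("simulate", "niche", "filter", "phenotype", "rates")


@dataclass
class RunConfig:
    """Parameters of one pipeline run (TOML-loadable; see ``from_toml``)."""

    seed: int = 0
    outdir: str = "run"
    world: WorldConfig = field(default_factory=WorldConfig)
    genotypes: GenoSimParams = field(default_factory=GenoSimParams)
    phenotypes: PhenoSimParams = field(default_factory=PhenoSimParams)
    source_only: bool = True      # native side of the niche model: source pops only
    coverage: float = 0.99
    n_env_samples: int = 50
    env_radius_km: float = 50.0
    alpha: float = 0.05
    n_nodes: int = 15
    years: float = rates.DEFAULT_YEARS
    epsilon: float = rates.DEFAULT_EPSILON
    stages: tuple[str, ...] = STAGES

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kwargs = {k: v for k, v in raw.items()
                  if k not in ("world", "genotypes", "phenotypes")}
        if "world" in raw:
            w = dict(raw["world"])
            for key in ("invaded_lons", "native_lat_range", "invaded_lat_range",
                        "source_lat_band"):
                if key in w:
                    w[key] = tuple(w[key])
            kwargs["world"] = WorldConfig(**w)
        if "genotypes" in raw:
            kwargs["genotypes"] = GenoSimParams(**raw["genotypes"])
        if "phenotypes" in raw:
            p = dict(raw["phenotypes"])
            if "cutpoints" in p:
                p["cutpoints"] = tuple(p["cutpoints"])
            if "severities" in p:
                p["severities"] = {k: tuple(v) for k, v in p["severities"].items()}
            kwargs["phenotypes"] = PhenoSimParams(**p)
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        return cls(**kwargs)


def child_seed(global_seed: int, stage: str) -> int:
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([global_seed, idx]).generate_state(1)[0] % (2 ** 31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, msg: str):
        super().__init__(f"stage {stage!r} failed: {msg}")
        self.stage = stage


def _require(outdir: Path, stage: str, *names: str) -> None:
    for name in names:
        if not (outdir / name).exists():
            raise PipelineError(stage, f"missing upstream output {name!r}")


def stage_simulate(config: RunConfig, outdir: Path) -> dict:
    world_cfg = dataclasses.replace(config.world,
                                    seed=child_seed(config.seed, "simulate"))
    world = make_world(world_cfg)
    genotypes, truth = make_genotypes(world, config.genotypes,
                                      seed=child_seed(config.seed, "filter"))
    phenotypes = make_phenotypes(world, config.phenotypes,
                                 seed=child_seed(config.seed, "phenotype"))
    world.occurrences.to_csv(outdir / "occurrences.csv", index=False)
    write_env_dir(outdir / "env", world.env)
    genotypes.to_csv(outdir / "genotypes.csv", index=False)
    phenotypes.to_csv(outdir / "phenotypes.csv", index=False)
    (outdir / "truth.json").write_text(json.dumps(
        truth.to_dict(orient="records"), indent=1))
    background = pd.concat(world.coastal_cells.values(), ignore_index=True)
    background.to_csv(outdir / "background.csv", index=False)
    return {"world": world, "genotypes": genotypes, "truth": truth,
            "phenotypes": phenotypes, "background": background}


def run_niche_analysis(occ: pd.DataFrame, background: pd.DataFrame, grid,
                       source_only: bool = True, coverage: float = 0.99,
                       n_samples: int = 50, radius_km: float = 50.0,
                       seed: int = 0) -> dict:
    """The niche-shift analysis on in-memory inputs (no file I/O).

    Returns the fitted PCA-env model, retained variables, per-point
    scores, the O/E/U classification and the centroid shift.
    """
    bg_env = env_niche.extract_env_table(background, grid, n_samples,
                                         radius_km, seed=seed)
    occ_env = env_niche.extract_env_table(occ, grid, n_samples,
                                          radius_km, seed=seed + 1)
    retained_vars = env_niche.filter_correlated(bg_env)
    model = env_niche.fit_pcaenv(bg_env[retained_vars], occ_env[retained_vars])
    occ_scores = model.occurrence_scores[:, :2]

    native_mask = (occ["range_class"] == "native_source") if source_only \
        else occ["range_class"].str.startswith("native")
    invaded_mask = occ["range_class"] == "invaded"
    nat_scores = occ_scores[native_mask.to_numpy()]
    inv_scores = occ_scores[invaded_mask.to_numpy()]
    grid_xy = env_niche.shared_grid(nat_scores, inv_scores)
    nat_region = env_niche.kde_region(nat_scores, coverage, grid=grid_xy)
    inv_region = env_niche.kde_region(inv_scores, coverage, grid=grid_xy)
    pop_scores = env_niche.population_scores(occ, occ_scores)
    classification = env_niche.classify_niche(nat_region, inv_region, pop_scores)
    classification.centroid_shift = env_niche.centroid_shift(nat_scores,
                                                             inv_scores)
    return {"model": model, "classification": classification,
            "retained_vars": retained_vars,
            "centroid_shift": classification.centroid_shift,
            "occ_scores": occ_scores, "occ_env": occ_env}


def stage_niche(config: RunConfig, outdir: Path, state: dict) -> dict:
    from .rasters import read_env_dir

    _require(outdir, "niche", "occurrences.csv", "background.csv", "env")
    occ = pd.read_csv(outdir / "occurrences.csv")
    background = pd.read_csv(outdir / "background.csv")
    grid = state["world"].env if "world" in state else read_env_dir(outdir / "env")
    seed = child_seed(config.seed, "niche")

    res = run_niche_analysis(occ, background, grid,
                             source_only=config.source_only,
                             coverage=config.coverage,
                             n_samples=config.n_env_samples,
                             radius_km=config.env_radius_km, seed=seed)
    model = res["model"]
    classification = res["classification"]
    occ_scores = res["occ_scores"]
    shift = res["centroid_shift"]
    retained_vars = res["retained_vars"]
    occ_env = res["occ_env"]

    (outdir / "pca_model.json").write_text(json.dumps(model.to_dict(), indent=1))
    scores = occ[["id", "population", "range_class", "coastline"]].copy()
    scores["PC1"], scores["PC2"] = occ_scores[:, 0], occ_scores[:, 1]
    scores.to_csv(outdir / "scores.csv", index=False)
    classification.populations.to_csv(outdir / "niche_labels.csv", index=False)
    cells = pd.DataFrame({
        "x": np.repeat(classification.x, len(classification.y)),
        "y": np.tile(classification.y, len(classification.x)),
        "label": classification.cell_labels.T.ravel(),
    })
    cells.to_csv(outdir / "region_cells.csv", index=False)
    (outdir / "centroid_shift.json").write_text(json.dumps(
        {"dPC1": shift[0], "dPC2": shift[1]}))
    return {"model": model, "classification": classification,
            "retained_vars": retained_vars, "centroid_shift": shift,
            "occ_env": occ_env}


def stage_filter(config: RunConfig, outdir: Path, state: dict) -> dict:
    _require(outdir, "filter", "genotypes.csv")
    genotypes = pd.read_csv(outdir / "genotypes.csv")
    report = popgen.dedupe(genotypes, alpha=config.alpha)
    report.thallus_table.to_csv(outdir / "clone_report.csv", index=False)
    pd.DataFrame({"thallus": report.retained}).to_csv(
        outdir / "retained_thalli.csv", index=False)
    report.population_summary.to_csv(outdir / "clone_summary.csv", index=False)
    return {"clone_report": report}


def _filtered_assays(outdir: Path) -> pd.DataFrame:
    assays = pd.read_csv(outdir / "phenotypes.csv")
    genotyped = set(pd.read_csv(outdir / "genotypes.csv")["thallus"])
    retained = set(pd.read_csv(outdir / "retained_thalli.csv")["thallus"])
    dropped = genotyped - retained
    return assays[~assays["thallus"].isin(dropped)]


def stage_phenotype(config: RunConfig, outdir: Path, state: dict) -> dict:
    _require(outdir, "phenotype", "phenotypes.csv", "retained_thalli.csv",
             "niche_labels.csv", "occurrences.csv")
    assays = _filtered_assays(outdir)
    if len(assays) == 0:
        raise PipelineError("phenotype", "no assays left after clone filtering")
    labels = pd.read_csv(outdir / "niche_labels.csv")
    occ = pd.read_csv(outdir / "occurrences.csv")
    grid = state["world"].env if "world" in state else None
    if grid is None:
        from .rasters import read_env_dir
        grid = read_env_dir(outdir / "env")
    pop_info = occ[["population", "lat", "coastline", "range_class"]].copy()
    pop_info["sstmax"] = [grid.value_at("SSTmax", r.lon, r.lat)
                          for r in occ.itertuples()]

    tables = {}
    for stressor in assays["stressor"].unique():
        tab = ordinal.deviance_table(assays, stressor, n_nodes=config.n_nodes)
        tab.to_frame().to_csv(outdir / f"deviance_{stressor}.csv", index=False)
        tables[stressor] = tab

    heat = "heat40" if "heat40" in tables else next(iter(tables))
    top_level = assays.loc[assays["stressor"] == heat, "level"].iloc[-1]
    try:
        fit, p, means = ordinal.ove_contrast(assays[assays["stressor"] == heat],
                                             labels, level=top_level,
                                             n_nodes=config.n_nodes)
        ove = {"stressor": heat, "level": str(top_level), "p": p,
               "mean_sbs": {k: float(v) for k, v in means.items()},
               "beta_E": float(fit.beta.get("E", np.nan))}
    except ValueError as exc:
        # a niche class can be empty on some worlds; record, don't abort
        ove = {"stressor": heat, "level": str(top_level), "p": None,
               "mean_sbs": {}, "error": str(exc)}
        p, means = None, {}
    (outdir / "ove_contrast.json").write_text(json.dumps(ove, indent=1))

    cline = ordinal.cline_model(assays[assays["stressor"] == heat], pop_info,
                                level=top_level, n_nodes=config.n_nodes)
    cline["curves"].to_csv(outdir / "cline_curves.csv", index=False)
    (outdir / "cline_fit.json").write_text(json.dumps({
        "level": str(top_level),
        "coefficients": {k: float(v) for k, v in cline["fit"].beta.items()},
        "rows": cline["rows"].rows,
        "sst_lat_r2": cline.get("sst_lat_r2", {}),
    }, indent=1))
    return {"deviance": tables, "ove": {"p": p, "means": means},
            "cline": cline, "assays": assays}


def stage_rates(config: RunConfig, outdir: Path, state: dict) -> dict:
    _require(outdir, "rates", "phenotypes.csv", "retained_thalli.csv")
    assays = _filtered_assays(outdir)
    table = rates.assay_darwin_rates(assays, years=config.years,
                                     epsilon=config.epsilon)
    summary = rates.rate_summary(table)
    table.to_csv(outdir / "darwin_rates.csv", index=False)
    summary.rename("mean_rate").to_csv(outdir / "darwin_rate_summary.csv")
    return {"darwin_rates": table, "rate_summary": summary}


_STAGE_FUNCS = {
    "simulate": lambda cfg, out, st: stage_simulate(cfg, out),
    "niche": stage_niche,
    "filter": stage_filter,
    "phenotype": stage_phenotype,
    "rates": stage_rates,
}


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages in dependency order; write a manifest.

    Returns the in-memory state dict with each stage's principal objects.
    Failures raise :class:`PipelineError` naming the failing stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        try:
            state.update(_STAGE_FUNCS[stage](config, outdir, state))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
    manifest = {
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {
            "source_only": config.source_only, "coverage": config.coverage,
            "alpha": config.alpha, "n_nodes": config.n_nodes,
            "years": config.years, "epsilon": config.epsilon,
            "world": dataclasses.asdict(config.world) | {"climate": {
                k: dataclasses.asdict(v) for k, v in config.world.climate.items()}},
            "genotypes": dataclasses.asdict(config.genotypes),
            "phenotypes": dataclasses.asdict(config.phenotypes),
        },
        "checksums": {p.name: _sha256(p) for p in sorted(outdir.glob("*.csv"))
                      + sorted(outdir.glob("*.json")) if p.name != "manifest.json"},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return state
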