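"""Seeded synthetic worlds: coastlines, climate layers, occurrences,
microsatellite genotypes, and ordinal bleaching phenotypes.

The generator reproduces the statistical structure the analysis assumes
for an invasive coastal seaweed:

* a native coastline whose *source* populations sit in a cold,
  strongly seasonal latitude band, and one or more invaded coastlines
  extending into warmer, less seasonal climate space;
* climate layers that are smooth latitudinal gradients plus noise, with
  maximum temperatures falling with |latitude| (so SSTmax inversely
  correlates with latitude along a coastline, as in the real system);
* populations of ~16 genotyped thalli containing diploids, haploids and
  clonal replicates, with a truth table for downstream recovery tests;
* per-thallus ordinal bleaching scores (1 none / 2 partial / 3 full)
  under a control and three stressor severities, generated from a
  latent-logistic cumulative-link model with population random
  intercepts, a region effect and an SST-linked tolerance cline.

All randomness flows from explicit seeds via numpy Generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .env_niche import build_coastal_background
from .rasters import CLIMATE_VARIABLES, EnvGrid

STRESSORS = ("heat40", "coldm20", "salinity")
#: Treatment levels per stressor: hours at 40 degC, minutes at -20 degC, ppt.
STRESSOR_LEVELS = {
    "heat40": ("1hr", "2hr", "4hr"),
    "coldm20": ("45min", "75min", "105min"),
    "salinity": ("0ppt", "5ppt", "10ppt"),
}


@dataclass(frozen=True)
class GradientParams:
    """Analytic climate field for one variable (units of the variable).

    value(lon, lat) = intercept + lat_slope * |lat|
                      + seasonal_amp * cos(pi * (lon - native_lon) / 180)
                      + invaded_temp_offset on invaded-side cells
                        (temperature-level variables only)
                      + smooth regional anomaly field (sd smooth_sd)
                      + N(0, noise_sd) per cell

    The smooth anomaly is a seeded mixture of long-wavelength sinusoids
    specific to each variable. It plays the role of regional climate
    structure not explained by latitude, and keeps cross-variable
    correlations below 1 the way real climatologies are: without it,
    every layer would be the same latitudinal ramp plus white noise and
    the <.9 correlation filter would collapse the variable set.
    """

    intercept: float
    lat_slope: float
    seasonal_amp: float = 0.0
    noise_sd: float = 0.5
    smooth_sd: float = 0.0

    def __post_init__(self):
        if self.noise_sd < 0 or self.smooth_sd < 0:
            raise ValueError("noise_sd and smooth_sd must be >= 0")


# Defaults loosely emulate north-temperate coastal climates: temperatures
# fall with |latitude|; seasonal ranges are larger on the native (western
# Pacific style) coast via the longitudinal seasonality term.
DEFAULT_CLIMATE: dict[str, GradientParams] = {
    "SAL":      GradientParams(34.0, -0.05, 0.0, 0.3, 0.5),
    "SATmax":   GradientParams(36.0, -0.45, 0.3, 0.5, 1.6),
    "SATmean":  GradientParams(28.0, -0.50, 0.1, 0.4, 1.8),
    "SATmin":   GradientParams(20.0, -0.60, -0.3, 0.5, 2.2),
    "SATrange": GradientParams(6.0, 0.20, 0.4, 0.4, 0.9),
    "SSTmax":   GradientParams(32.0, -0.42, 0.2, 0.3, 1.0),
    "SSTmean":  GradientParams(27.0, -0.45, 0.1, 0.3, 1.5),
    "SSTmin":   GradientParams(22.0, -0.50, -0.2, 0.4, 1.8),
    "SSTrange": GradientParams(3.0, 0.18, 0.3, 0.3, 0.8),
    "PREC-01":  GradientParams(120.0, -0.8, 2.0, 6.0, 5.0),
    "PREC-04":  GradientParams(90.0, 0.3, -1.0, 5.0, 4.0),
    "PREC-07":  GradientParams(140.0, -1.0, 2.0, 8.0, 6.0),
    "PREC-10":  GradientParams(100.0, -0.2, 1.0, 6.0, 4.0),
}


@dataclass(frozen=True)
class WorldConfig:
    """Geometry and climate of a synthetic two-continent world.

    The native coastline is a meridional polyline at ``native_lon``;
    invaded coastlines sit at ``invaded_lons`` (one per invaded
    "continent"). Source populations are restricted to
    ``source_lat_band`` on the native coast; ``invaded_temp_offset``
    warms the sea and air temperature layers on the invaded side, so
    low-latitude invaded sites reach beyond the warm edge of the
    source climate while high-latitude ones remain inside it.
    """

    seed: int = 0
    n_native_pops: int = 15
    n_source_pops: int = 6
    n_invaded_pops: int = 10           # per invaded coastline
    n_invaded_coastlines: int = 1
    resolution: float = 1.0            # degrees
    native_lon: float = 140.25
    invaded_lons: tuple[float, ...] = (-70.5, -120.5, 0.5)
    native_lat_range: tuple[float, float] = (25.0, 46.0)
    invaded_lat_range: tuple[float, float] = (25.0, 50.0)
    source_lat_band: tuple[float, float] = (38.0, 46.0)
    invaded_temp_offset: float = 1.5   # degC warming of invaded-side temperatures
    divide_lon: float = 60.0           # cells west of this are "invaded side"
    climate: dict[str, GradientParams] = field(default_factory=lambda: dict(DEFAULT_CLIMATE))

    def __post_init__(self):
        if self.n_source_pops > self.n_native_pops:
            raise ValueError("n_source_pops must be <= n_native_pops")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if not set(self.climate) >= set(CLIMATE_VARIABLES):
            missing = set(CLIMATE_VARIABLES) - set(self.climate)
            raise ValueError(f"climate params missing for {sorted(missing)}")
        if self.n_invaded_coastlines > len(self.invaded_lons):
            raise ValueError("not enough invaded_lons for n_invaded_coastlines")


def analytic_field(var: str, lon, lat, config: WorldConfig) -> np.ndarray:
    """Noise-free value of one climate layer at (lon, lat)."""
    p = config.climate[var]
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    val = (p.intercept + p.lat_slope * np.abs(lat)
           + p.seasonal_amp * np.cos(np.pi * (lon - config.native_lon) / 180.0))
    if var in ("SSTmax", "SSTmean", "SSTmin", "SATmax", "SATmean", "SATmin"):
        val = val + np.where(lon < config.divide_lon, config.invaded_temp_offset, 0.0)
    return val


def _smooth_anomaly(lon, lat, sd: float, rng: np.random.Generator,
                    n_waves: int = 4) -> np.ndarray:
    """Seeded long-wavelength anomaly field with marginal sd ~ ``sd``.

    A mixture of sinusoids with wavelengths of 4-12 degrees in random
    directions; broad enough to survive 50-km disk averaging.
    """
    out = np.zeros_like(np.asarray(lon, dtype=float))
    for _ in range(n_waves):
        wavelength = rng.uniform(4.0, 12.0)
        theta = rng.uniform(0.0, 2 * np.pi)
        phase = rng.uniform(0.0, 2 * np.pi)
        out = out + np.sin(2 * np.pi * (np.cos(theta) * lon + np.sin(theta) * lat)
                           / wavelength + phase)
    return sd * np.sqrt(2.0 / n_waves) * out


@dataclass
class SyntheticWorld:
    config: WorldConfig
    coastlines: dict[str, np.ndarray]      # name -> (n, 2) lon/lat polyline
    env: EnvGrid
    occurrences: pd.DataFrame              # id, lon, lat, population, range_class, coastline
    coastal_cells: dict[str, pd.DataFrame] # name -> background cell centers


def _coastline_names(config: WorldConfig) -> list[str]:
    if config.n_invaded_coastlines == 1:
        return ["invaded"]
    return [f"invaded{k + 1}" for k in range(config.n_invaded_coastlines)]


def make_world(config: WorldConfig) -> SyntheticWorld:
    """Build coastlines, climate rasters and population occurrences.

    Occurrence points are population locations snapped to coastal cell
    centers; the same seed yields an identical world.
    """
    rng = np.random.default_rng(config.seed)
    res = config.resolution

    coastlines = {"native": np.array([[config.native_lon, config.native_lat_range[0]],
                                      [config.native_lon, config.native_lat_range[1]]])}
    for name, lon in zip(_coastline_names(config), config.invaded_lons):
        coastlines[name] = np.array([[lon, config.invaded_lat_range[0]],
                                     [lon, config.invaded_lat_range[1]]])

    # grid covering both continents with margin
    all_lons = [config.native_lon] + list(config.invaded_lons[:config.n_invaded_coastlines])
    lon_lo = np.floor(min(all_lons) / res) * res - 5 * res
    lon_hi = np.ceil(max(all_lons) / res) * res + 5 * res
    lat_lo = np.floor(min(config.native_lat_range[0], config.invaded_lat_range[0])) - 5 * res
    lat_hi = np.ceil(max(config.native_lat_range[1], config.invaded_lat_range[1])) + 5 * res
    ncols = int(round((lon_hi - lon_lo) / res))
    nrows = int(round((lat_hi - lat_lo) / res))
    lon_c = lon_lo + (np.arange(ncols) + 0.5) * res
    lat_c = lat_lo + (nrows - 0.5 - np.arange(nrows)) * res  # row 0 north
    glon, glat = np.meshgrid(lon_c, lat_c)

    layers = {}
    for var in CLIMATE_VARIABLES:
        p = config.climate[var]
        field_val = analytic_field(var, glon, glat, config)
        if p.smooth_sd > 0:
            field_val = field_val + _smooth_anomaly(glon, glat, p.smooth_sd, rng)
        if p.noise_sd > 0:
            field_val = field_val + rng.normal(0.0, p.noise_sd, size=glon.shape)
        layers[var] = field_val
    env = EnvGrid(lon_lo, lat_lo, res, layers)

    coastal_cells = {name: build_coastal_background([line], res)
                     for name, line in coastlines.items()}
    if all(len(c) == 0 for c in coastal_cells.values()):
        raise ValueError("empty world: no coastal cells")

    records = []
    band_lo, band_hi = config.source_lat_band

    def pick(cells: pd.DataFrame, n: int, label: str) -> pd.DataFrame:
        if n > len(cells):
            raise ValueError(f"empty world: not enough coastal cells for {label}")
        idx = rng.choice(len(cells), size=n, replace=False)
        return cells.iloc[np.sort(idx)]

    nat = coastal_cells["native"]
    in_band = nat[(nat.lat >= band_lo) & (nat.lat <= band_hi)]
    out_band = nat[~nat.index.isin(in_band.index)]
    src = pick(in_band, config.n_source_pops, "source populations")
    non = pick(out_band, config.n_native_pops - config.n_source_pops,
               "nonsource populations")
    for cls, cells in (("native_source", src), ("native_nonsource", non)):
        for _, row in cells.iterrows():
            records.append((row.lon, row.lat, cls, "native"))
    for name in _coastline_names(config):
        cells = pick(coastal_cells[name], config.n_invaded_pops, f"{name} populations")
        for _, row in cells.iterrows():
            records.append((row.lon, row.lat, "invaded", name))

    occ = pd.DataFrame(records, columns=["lon", "lat", "range_class", "coastline"])
    occ.insert(0, "population", [f"p{i + 1:03d}" for i in range(len(occ))])
    occ.insert(0, "id", [f"occ{i + 1:03d}" for i in range(len(occ))])
    return SyntheticWorld(config=config, coastlines=coastlines, env=env,
                          occurrences=occ, coastal_cells=coastal_cells)


# ---------------------------------------------------------------------------
# genotypes


@dataclass(frozen=True)
class GenoSimParams:
    """Microsatellite genotype simulation settings.

    Allele frequencies per locus/population are Dirichlet draws; clones
    are exact multilocus-genotype copies of a diploid progenitor in the
    same population; haploids carry a single allele per locus.
    """

    n_loci: int = 10
    n_alleles: int = 8
    dirichlet_conc: float = 1.0
    clone_fraction: float = 0.0
    haploid_fraction: float = 0.0
    thalli_per_pop: int = 16

    def __post_init__(self):
        if not (0 <= self.clone_fraction <= 1 and 0 <= self.haploid_fraction <= 1):
            raise ValueError("fractions must be in [0, 1]")
        if self.clone_fraction + self.haploid_fraction > 1:
            raise ValueError("clone + haploid fraction must be <= 1")
        if self.n_loci < 1 or self.n_alleles < 2:
            raise ValueError("need n_loci >= 1 and n_alleles >= 2")


def locus_names(n_loci: int) -> list[str]:
    return [f"L{i + 1:02d}" for i in range(n_loci)]


def make_genotypes(world: SyntheticWorld, params: GenoSimParams, seed: int,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-thallus multilocus genotypes plus a planted-truth table.

    Returns ``(genotypes, truth)``. Genotype columns are
    ``population, thallus, L01_a1, L01_a2, ...`` with allele sizes as
    positive integers and 0 = missing (haploids have ``_a2 = 0``). The
    truth table records each thallus's genet id, ploidy, role
    (``genet`` / ``clone`` / ``haploid``) and clonal progenitor.
    """
    if len(world.occurrences) == 0:
        raise ValueError("world has no populations")
    rng = np.random.default_rng(seed)
    loci = locus_names(params.n_loci)
    # fragment sizes: allele k at locus l -> 100 + 10*l + 2*k
    sizes = [100 + 10 * l + 2 * np.arange(params.n_alleles)
             for l in range(params.n_loci)]

    n = params.thalli_per_pop
    n_clone = int(round(params.clone_fraction * n))
    n_hap = int(round(params.haploid_fraction * n))
    n_genet = n - n_clone - n_hap
    if n_genet < 1 and n_clone > 0:
        raise ValueError("no diploid genets left to serve as clonal progenitors")

    geno_rows, truth_rows = [], []
    for pop in world.occurrences["population"]:
        freqs = rng.dirichlet(np.full(params.n_alleles, params.dirichlet_conc),
                              size=params.n_loci)
        seen: set[tuple] = set()

        def draw_diploid() -> tuple:
            for _ in range(200):
                mlg = []
                for l in range(params.n_loci):
                    a, b = rng.choice(sizes[l], size=2, p=freqs[l])
                    mlg.extend(sorted((int(a), int(b))))
                mlg = tuple(mlg)
                if mlg not in seen:
                    seen.add(mlg)
                    return mlg
            raise RuntimeError("could not draw a distinct diploid MLG")

        genets = [draw_diploid() for _ in range(n_genet)]
        entries = [("genet", i, None) for i in range(n_genet)]
        entries += [("clone", int(rng.integers(n_genet)), None) for _ in range(n_clone)]
        entries += [("haploid", None, None) for _ in range(n_hap)]
        order = rng.permutation(len(entries))
        for pos, j in enumerate(order):
            role, gi, _ = entries[j]
            thallus = f"{pop}-t{pos + 1:02d}"
            if role == "haploid":
                mlg = []
                for l in range(params.n_loci):
                    a = int(rng.choice(sizes[l], p=freqs[l]))
                    mlg.extend([a, 0])
                genet_id = f"{pop}-hap{j}"
                progenitor_idx = None
            else:
                mlg = list(genets[gi])
                genet_id = f"{pop}-g{gi + 1:02d}"
                progenitor_idx = gi if role == "clone" else None
            geno_rows.append([pop, thallus] + mlg)
            truth_rows.append([pop, thallus, genet_id,
                               "haploid" if role == "haploid" else "diploid",
                               role, progenitor_idx])

    cols = ["population", "thallus"]
    for l in loci:
        cols += [f"{l}_a1", f"{l}_a2"]
    genotypes = pd.DataFrame(geno_rows, columns=cols)
    truth = pd.DataFrame(truth_rows, columns=["population", "thallus", "genet_id",
                                              "ploidy", "role", "progenitor_index"])
    # resolve clonal progenitor thallus ids
    prog = []
    for row in truth.itertuples():
        if row.role == "clone":
            sib = truth[(truth.population == row.population)
                        & (truth.genet_id == row.genet_id) & (truth.role == "genet")]
            prog.append(sib.thallus.iloc[0] if len(sib) else None)
        else:
            prog.append(None)
    truth["progenitor"] = prog
    truth = truth.drop(columns=["progenitor_index"])
    return genotypes, truth


# ---------------------------------------------------------------------------
# phenotypes


@dataclass(frozen=True)
class PhenoSimParams:
    """Latent-logistic ordinal bleaching model.

    A thallus's latent bleaching propensity is

        eta = severity(level) + beta_region * [invaded]
              + beta_sst * (SSTmax_pop - mean SSTmax) + u_pop,
        u_pop ~ N(0, sigma_pop^2),

    and its bleaching score is ordinal-logistic with the given cutpoints:
    P(BS <= k) = expit(cutpoints[k] - eta). Controls are drawn at zero
    severity; the default cutpoints put ~10% partial/full bleaching in
    controls (control bleaching is possible but rare, so negative
    standardized scores occur at low frequency).
    """

    cutpoints: tuple[float, float] = (2.2, 4.0)
    beta_region: float = -1.5          # invaded populations more tolerant
    beta_sst: float = -0.15            # warmer-site populations more tolerant
    sigma_pop: float = 0.5
    severities: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"heat40": (1.0, 2.5, 4.0),
                                 "coldm20": (1.0, 2.0, 3.5),
                                 "salinity": (2.0, 1.5, 1.0)})
    thalli_per_pop: int = 20
    stage: str = "field"

    def __post_init__(self):
        if list(self.cutpoints) != sorted(self.cutpoints) or \
                len(set(self.cutpoints)) != len(self.cutpoints):
            raise ValueError("cutpoints must be strictly increasing")
        if self.sigma_pop < 0:
            raise ValueError("sigma_pop must be >= 0")


def draw_bs(eta: np.ndarray, cutpoints, rng: np.random.Generator) -> np.ndarray:
    """Draw ordinal scores 1..K from the cumulative-logistic model."""
    eta = np.asarray(eta, dtype=float)
    cum = expit(np.subtract.outer(np.asarray(cutpoints, float), eta))  # (K-1, n)
    u = rng.uniform(size=eta.shape)
    return 1 + (u > cum).sum(axis=0)


def make_phenotypes(world: SyntheticWorld, params: PhenoSimParams, seed: int,
                    stressors=STRESSORS, pop_effects=None) -> pd.DataFrame:
    """Simulate the bleaching-assay table.

    One row per thallus x stressor x treatment level, with a shared
    control score per thallus x stressor (one control apex per thallus).
    Columns: thallus, population, coastline, range_class, stressor,
    level, stage, bs_control, bs_treatment, sbs.

    ``pop_effects`` optionally maps population codes to additional
    latent offsets (e.g. a tolerance advantage planted for populations
    classified into the expansion niche).
    """
    rng = np.random.default_rng(seed)
    occ = world.occurrences
    if params.thalli_per_pop == 0 or len(occ) == 0:
        return pd.DataFrame(columns=["thallus", "population", "coastline",
                                     "range_class", "stressor", "level", "stage",
                                     "bs_control", "bs_treatment", "sbs"])
    sst = np.array([world.env.value_at("SSTmax", r.lon, r.lat)
                    for r in occ.itertuples()])
    sst_c = sst - sst.mean()
    rows = []
    for (i, pop_row), sst_dev in zip(enumerate(occ.itertuples()), sst_c):
        u_pop = rng.normal(0.0, params.sigma_pop) if params.sigma_pop > 0 else 0.0
        invaded = pop_row.range_class == "invaded"
        extra = 0.0 if pop_effects is None else float(
            pop_effects.get(pop_row.population, 0.0))
        base = (params.beta_region * invaded + params.beta_sst * sst_dev
                + u_pop + extra)
        for t in range(params.thalli_per_pop):
            thallus = f"{pop_row.population}-t{t + 1:02d}"
            for stressor in stressors:
                levels = STRESSOR_LEVELS[stressor]
                bs_ctrl = int(draw_bs(np.array([base]), params.cutpoints, rng)[0])
                sev = params.severities[stressor]
                eta = base + np.asarray(sev, dtype=float)
                bs_trt = draw_bs(eta, params.cutpoints, rng)
                for lvl, bt in zip(levels, bs_trt):
                    rows.append([thallus, pop_row.population, pop_row.coastline,
                                 pop_row.range_class, stressor, lvl, params.stage,
                                 bs_ctrl, int(bt), int(bt) - bs_ctrl])
    return pd.DataFrame(rows, columns=["thallus", "population", "coastline",
                                       "range_class", "stressor", "level", "stage",
                                       "bs_control", "bs_treatment", "sbs"])
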