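"""Environmental-niche ordination and niche-shift classification.

The analysis chain implemented here:

1. grid the world's coastlines into 1-degree cells and keep the cell
   centers as "potential habitat" background points;
2. for each background/occurrence point, average each climate variable
   over random points within a 50-km great-circle disk;
3. drop highly correlated variables, then run a correlation PCA
   (center + unit-scale) over background and occurrence rows jointly,
   giving a 2-D climate ordination ("PCA-env");
4. estimate 99% kernel-density regions for the native-source and the
   invaded score clouds and classify niche space into Overlap (O,
   shared), Expansion (E, invaded only) and Unfilled (U, native only);
5. report per-population labels and the centroid shift between ranges.

Populations in the E region occupy climates absent from the native
source range, the signature from which downstream phenotypic-evolution
predictions are made.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EARTH_RADIUS_KM = 6371.0088

RANGE_CLASSES = ("native_source", "native_nonsource", "invaded")


def normalize_lon(lon):
    """Wrap longitudes into [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371.0088 km."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


# ---------------------------------------------------------------------------
# background grid


def _split_antimeridian(polyline: np.ndarray) -> list[np.ndarray]:
    """Split a polyline wherever consecutive vertices jump across the antimeridian."""
    pts = np.column_stack([normalize_lon(polyline[:, 0]), polyline[:, 1]])
    pieces, start = [], 0
    for i in range(1, len(pts)):
        if abs(pts[i, 0] - pts[i - 1, 0]) > 180.0:
            pieces.append(pts[start:i])
            start = i
    pieces.append(pts[start:])
    return [p for p in pieces if len(p) >= 1]


def _segment_cells(x0, y0, x1, y1, cell: float) -> set[tuple[int, int]]:
    """Grid cells traversed by one segment, half-open [i*c, (i+1)*c) convention.

    Exact traversal: cut the segment at every gridline crossing and take the
    cell of each sub-segment midpoint (plus the endpoints' cells).
    """
    ts = [0.0, 1.0]
    for (a0, a1) in ((x0, x1), (y0, y1)):
        lo, hi = sorted((a0, a1))
        k = math.ceil(lo / cell)
        while k * cell <= hi:
            v = k * cell
            if a1 != a0:
                t = (v - a0) / (a1 - a0)
                if 0.0 < t < 1.0:
                    ts.append(t)
            k += 1
    ts = sorted(set(ts))
    cells = set()
    for t in ts:  # endpoints and crossing points themselves
        x, y = x0 + t * (x1 - x0), y0 + t * (y1 - y0)
        cells.add((math.floor(x / cell), math.floor(y / cell)))
    for ta, tb in zip(ts[:-1], ts[1:]):
        t = 0.5 * (ta + tb)
        x, y = x0 + t * (x1 - x0), y0 + t * (y1 - y0)
        cells.add((math.floor(x / cell), math.floor(y / cell)))
    return cells


def build_coastal_background(polylines, cell_deg: float = 1.0) -> pd.DataFrame:
    """Centers of every grid cell intersected by any coastline polyline.

    Parameters
    ----------
    polylines : iterable of (n, 2) arrays
        Coastline vertices as (lon, lat) in WGS84 degrees.
    cell_deg : float
        Cell size in degrees (the analysis default is a 1x1-degree grid).

    Returns
    -------
    DataFrame with columns ``lon, lat`` — sorted, deduplicated cell centers.
    """
    if cell_deg <= 0:
        raise ValueError("cell_deg must be > 0")
    cells: set[tuple[int, int]] = set()
    for line in polylines:
        line = np.asarray(line, dtype=float)
        if line.ndim != 2 or line.shape[1] != 2 or len(line) == 0:
            raise ValueError("polylines must be (n, 2) arrays of lon/lat")
        for piece in _split_antimeridian(line):
            if len(piece) == 1:
                x, y = piece[0]
                cells.add((math.floor(x / cell_deg), math.floor(y / cell_deg)))
                continue
            for (x0, y0), (x1, y1) in zip(piece[:-1], piece[1:]):
                cells |= _segment_cells(x0, y0, x1, y1, cell_deg)
    centers = sorted((ix * cell_deg + cell_deg / 2, iy * cell_deg + cell_deg / 2)
                     for ix, iy in cells)
    return pd.DataFrame(centers, columns=["lon", "lat"])


# ---------------------------------------------------------------------------
# buffered environmental extraction


def disk_points(lon: float, lat: float, radius_km: float, n: int,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Area-uniform random points within a great-circle disk.

    Radial distances use the sqrt(u) transform; the longitudinal offset is
    compressed by cos(lat). Accurate for the ~50-km radii used here.
    """
    r = radius_km * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2 * np.pi, size=n)
    dlat = np.degrees((r * np.cos(theta)) / EARTH_RADIUS_KM)
    dlon = np.degrees((r * np.sin(theta)) / (EARTH_RADIUS_KM * math.cos(math.radians(lat))))
    return normalize_lon(lon + dlon), lat + dlat


def extract_env(lon: float, lat: float, grid, n_samples: int = 50,
                radius_km: float = 50.0, rng=None, seed=None) -> pd.Series:
    """Mean of each climate variable over random points within a disk.

    Satellite-derived marine layers and terrestrial layers rarely cover the
    same coastal pixel, so each variable is averaged over ``n_samples``
    points inside a ``radius_km`` great-circle disk around the location,
    ignoring samples that fall on missing data.

    Raises ``ValueError`` naming the variable and point if every sample is
    missing for some variable.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    lons, lats = disk_points(lon, lat, radius_km, n_samples, rng)
    out = {}
    for var in grid.variables:
        vals = grid.interpolate(var, lons, lats)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(
                f"all {n_samples} samples hit nodata for variable {var!r} "
                f"at point ({lon}, {lat})")
        out[var] = float(vals.mean())
    return pd.Series(out)


def extract_env_table(points: pd.DataFrame, grid, n_samples: int = 50,
                      radius_km: float = 50.0, seed: int = 0) -> pd.DataFrame:
    """``extract_env`` over a table of points; one child RNG stream per point."""
    root = np.random.default_rng(seed)
    rows = [extract_env(p.lon, p.lat, grid, n_samples, radius_km,
                        rng=np.random.default_rng(root.integers(2 ** 31)))
            for p in points.itertuples()]
    return pd.DataFrame(rows, index=points.index)


# ---------------------------------------------------------------------------
# variable filtering and ordination


def filter_correlated(env: pd.DataFrame, threshold: float = 0.9) -> list[str]:
    """Greedily drop variables until all pairwise |Pearson r| < threshold.

    At each step the worst (largest |r|) remaining pair is found and the
    member with the larger mean |r| against all other remaining variables is
    dropped; ties drop the alphabetically later name.
    """
    if env.shape[1] < 2 or env.shape[0] < 3:
        raise ValueError("need at least 2 variables and 3 rows")
    if (env.std(ddof=1) == 0).any():
        bad = env.columns[env.std(ddof=1) == 0].tolist()
        raise ValueError(f"constant column(s) {bad}: correlation undefined")
    keep = list(env.columns)
    while len(keep) > 1:
        corr = env[keep].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.values.max()
        if worst < threshold:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        a, b = corr.columns[i], corr.columns[j]
        mean_a = corr.loc[a, [c for c in keep if c != a]].mean()
        mean_b = corr.loc[b, [c for c in keep if c != b]].mean()
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = max(a, b)
        keep.remove(drop)
    return keep


@dataclass
class PCAenvModel:
    """Correlation PCA over climate rows (background + occurrences).

    ``loadings`` has one orthonormal column per component; ``transform``
    centers and unit-scales new rows with the stored statistics before
    projection. Sign convention: the largest-|loading| entry of each
    component is positive.
    """

    variables: list[str]
    mean: pd.Series
    scale: pd.Series
    loadings: np.ndarray          # (n_vars, n_comp)
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    background_scores: np.ndarray
    occurrence_scores: np.ndarray | None = None

    def transform(self, env: pd.DataFrame) -> np.ndarray:
        z = (env[self.variables] - self.mean) / self.scale
        return z.to_numpy(dtype=float) @ self.loadings

    def correlations(self, env: pd.DataFrame, scores: np.ndarray) -> pd.DataFrame:
        """Variable-vs-axis Pearson correlations (the loading-plot table)."""
        out = {}
        for k in range(scores.shape[1]):
            out[f"PC{k + 1}"] = [stats.pearsonr(env[v], scores[:, k])[0]
                                 for v in self.variables]
        return pd.DataFrame(out, index=self.variables)

    def to_dict(self) -> dict:
        return {
            "variables": self.variables,
            "mean": self.mean.to_dict(),
            "scale": self.scale.to_dict(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_fractions": self.variance_fractions.tolist(),
        }


def fit_pcaenv(background: pd.DataFrame, occurrences: pd.DataFrame | None = None,
               ) -> PCAenvModel:
    """Fit the PCA-env ordination on background + occurrence rows jointly.

    Variables are centered and scaled to unit variance over the combined
    rows (correlation PCA), so mixed units (degC, mm, salinity) are
    commensurable. All components are retained; variance fractions sum to 1.
    """
    variables = list(background.columns)
    rows = background if occurrences is None else pd.concat(
        [background[variables], occurrences[variables]], ignore_index=True)
    if len(rows) < 2:
        raise ValueError("need at least 2 rows to fit a PCA")
    if len(rows) < len(variables):
        raise ValueError("need at least as many rows as variables")
    mean = rows.mean()
    scale = rows.std(ddof=1)
    if (scale == 0).any():
        raise ValueError("constant variable(s); filter before fitting")
    z = ((rows - mean) / scale).to_numpy(dtype=float)
    # eigendecomposition of the correlation matrix via SVD of z
    _, svals, vt = np.linalg.svd(z, full_matrices=False)
    eigvals = svals ** 2 / (len(rows) - 1)
    loadings = vt.T
    # deterministic sign: largest-magnitude entry of each column positive
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
    model = PCAenvModel(
        variables=variables, mean=mean, scale=scale, loadings=loadings,
        eigenvalues=eigvals, variance_fractions=eigvals / eigvals.sum(),
        background_scores=np.empty((0, loadings.shape[1])),
    )
    model.background_scores = model.transform(background)
    if occurrences is not None:
        model.occurrence_scores = model.transform(occurrences)
    return model


# ---------------------------------------------------------------------------
# kernel-density niche regions


@dataclass
class DensityRegion:
    """A highest-density region of the 2-D ordination space.

    The region is the set of evaluation-grid cells of largest density whose
    cumulative normalized mass first reaches ``coverage`` (default 99%).
    """

    x: np.ndarray                # cell-center coordinates, ascending
    y: np.ndarray
    density: np.ndarray          # (ny, nx)
    mask: np.ndarray             # boolean, same shape
    threshold: float
    coverage: float
    bandwidth: np.ndarray        # 2x2 kernel covariance

    @property
    def cell_area(self) -> float:
        return float((self.x[1] - self.x[0]) * (self.y[1] - self.y[0]))

    @property
    def area(self) -> float:
        return float(self.mask.sum()) * self.cell_area

    def same_grid(self, other: "DensityRegion") -> bool:
        return (self.x.shape == other.x.shape and self.y.shape == other.y.shape
                and np.allclose(self.x, other.x) and np.allclose(self.y, other.y))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Membership of (n, 2) points; points off the evaluation grid are outside."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        dx = self.x[1] - self.x[0]
        dy = self.y[1] - self.y[0]
        ix = np.floor((pts[:, 0] - (self.x[0] - dx / 2)) / dx).astype(int)
        iy = np.floor((pts[:, 1] - (self.y[0] - dy / 2)) / dy).astype(int)
        ok = (ix >= 0) & (ix < self.x.size) & (iy >= 0) & (iy < self.y.size)
        out = np.zeros(len(pts), dtype=bool)
        out[ok] = self.mask[iy[ok], ix[ok]]
        return out


class _DiagonalKDE:
    """Gaussian KDE with a fixed diagonal bandwidth (degenerate-cloud fallback)."""

    def __init__(self, data: np.ndarray, sd: np.ndarray):
        self.data = data
        self.sd = sd
        self.covariance = np.diag(sd ** 2)

    def __call__(self, xy: np.ndarray) -> np.ndarray:
        z = (xy[:, None, :] - self.data[None, :, :]) / self.sd
        norm = 2 * np.pi * self.sd.prod() * len(self.data)
        return np.exp(-0.5 * (z ** 2).sum(-1)).sum(1) / norm


def kde_region(scores: np.ndarray, coverage: float = 0.99, grid_n: int = 200,
               pad_bandwidths: float = 3.0, grid=None) -> DensityRegion:
    """Gaussian-kernel 99% highest-density region of a 2-D score cloud.

    Bandwidth follows Scott's rule with the full sample covariance. The
    evaluation grid spans the data range padded by ``pad_bandwidths``
    marginal bandwidths (or use ``grid=(x, y)`` to force a shared grid when
    two regions must be compared cell-by-cell).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("scores must be (n, 2)")
    if len(scores) < 5:
        raise ValueError("need at least 5 points for a density region")
    if not (0 < coverage < 1):
        raise ValueError("coverage must be in (0, 1)")
    try:
        kde = stats.gaussian_kde(scores.T)
        bw = np.asarray(kde.covariance)
        evaluate = lambda xy: kde(xy.T)  # noqa: E731
    except np.linalg.LinAlgError:
        # all points (nearly) collinear or identical: floor the bandwidth
        sd = scores.std(axis=0, ddof=0)
        sd = np.maximum(sd, 1e-3 * max(1.0, float(np.abs(scores).max())))
        fallback = _DiagonalKDE(scores, sd)
        bw = fallback.covariance
        evaluate = fallback
    if grid is not None:
        x, y = (np.asarray(g, dtype=float) for g in grid)
    else:
        pad = pad_bandwidths * np.sqrt(np.diag(bw))
        x = np.linspace(scores[:, 0].min() - pad[0], scores[:, 0].max() + pad[0], grid_n)
        y = np.linspace(scores[:, 1].min() - pad[1], scores[:, 1].max() + pad[1], grid_n)
    xx, yy = np.meshgrid(x, y)
    dens = evaluate(np.column_stack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    order = np.argsort(dens.ravel())[::-1]
    mass = dens.ravel()[order]
    mass = mass / mass.sum()
    cum = np.cumsum(mass)
    k = int(np.searchsorted(cum, coverage)) + 1
    threshold = float(dens.ravel()[order[min(k - 1, len(order) - 1)]])
    mask = dens >= threshold
    return DensityRegion(x=x, y=y, density=dens, mask=mask, threshold=threshold,
                         coverage=coverage, bandwidth=bw)


def shared_grid(*score_sets, grid_n: int = 200, pad: float = 1.0):
    """An evaluation grid spanning several score clouds jointly."""
    allpts = np.vstack([np.asarray(s, dtype=float) for s in score_sets])
    lo = allpts.min(axis=0) - pad
    hi = allpts.max(axis=0) + pad
    return (np.linspace(lo[0], hi[0], grid_n), np.linspace(lo[1], hi[1], grid_n))


# ---------------------------------------------------------------------------
# niche classification


@dataclass
class NicheClassification:
    """Per-cell O/E/U partition and per-population labels.

    O = cells in both the native(-source) and invaded regions, E = invaded
    only (niche expansion), U = native only (unfilled niche); everything
    else is outside both regions.
    """

    cell_labels: np.ndarray      # str array ('O','E','U','outside'), (ny, nx)
    x: np.ndarray
    y: np.ndarray
    populations: pd.DataFrame    # population, PC1, PC2, label
    centroid_shift: tuple[float, float] | None = None

    def counts(self) -> dict[str, int]:
        lab, cnt = np.unique(self.cell_labels, return_counts=True)
        return dict(zip(lab.tolist(), cnt.tolist()))


def classify_niche(native_region: DensityRegion, invaded_region: DensityRegion,
                   population_scores: pd.DataFrame) -> NicheClassification:
    """Set-algebra O/E/U labels on a shared evaluation grid.

    ``population_scores`` needs columns ``population, PC1, PC2`` (one row
    per population; average member scores first if needed). Populations
    outside both regions are labeled ``outside``.
    """
    if not native_region.same_grid(invaded_region):
        raise ValueError(
            "regions evaluated on different grids; rebuild both with "
            "kde_region(..., grid=shared_grid(a, b))")
    nat, inv = native_region.mask, invaded_region.mask
    labels = np.full(nat.shape, "outside", dtype=object)
    labels[nat & inv] = "O"
    labels[inv & ~nat] = "E"
    labels[nat & ~inv] = "U"

    pts = population_scores[["PC1", "PC2"]].to_numpy(dtype=float)
    in_nat = native_region.contains(pts)
    in_inv = invaded_region.contains(pts)
    pop_label = np.where(in_nat & in_inv, "O",
                         np.where(in_inv, "E", np.where(in_nat, "U", "outside")))
    pops = population_scores.copy()
    pops["label"] = pop_label
    return NicheClassification(cell_labels=labels, x=native_region.x,
                               y=native_region.y, populations=pops)


def population_scores(occurrences: pd.DataFrame, scores: np.ndarray) -> pd.DataFrame:
    """Population-level scores: mean of member-occurrence scores per population."""
    df = occurrences[["population"]].copy()
    df["PC1"] = scores[:, 0]
    df["PC2"] = scores[:, 1]
    out = df.groupby("population", as_index=False).mean()
    meta_cols = [c for c in ("range_class", "coastline") if c in occurrences.columns]
    if meta_cols:
        meta = occurrences.groupby("population")[meta_cols].first().reset_index()
        out = out.merge(meta, on="population")
    return out


def centroid_shift(native_scores: np.ndarray, invaded_scores: np.ndarray,
                   ) -> tuple[float, float]:
    """Shift of the realized-niche centroid, invaded minus native."""
    nat = np.atleast_2d(np.asarray(native_scores, dtype=float))
    inv = np.atleast_2d(np.asarray(invaded_scores, dtype=float))
    if nat.size == 0 or inv.size == 0:
        raise ValueError("both score sets must be nonempty")
    d = inv.mean(axis=0) - nat.mean(axis=0)
    return float(d[0]), float(d[1])
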