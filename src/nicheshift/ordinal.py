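"""Ordinal bleaching statistics and cumulative-link (mixed) models.

Bleaching assays score each thallus 1 (no bleaching), 2 (partial) or 3
(full). The standardized bleach score ``SBS = BS_treatment - BS_control``
removes the per-thallus baseline and ranges over -2..2.

SBS is analyzed with proportional-odds (cumulative-logit) models:

    P(Y <= k | x) = expit(theta_k - x'beta),   theta_1 < ... < theta_{K-1},

optionally with a population random intercept u ~ N(0, sigma_pop^2) on
the latent scale. The mixed model's marginal likelihood integrates u by
adaptive Gauss-Hermite quadrature (default 15 nodes, centered and scaled
at each group's conditional mode). p-values come from likelihood-ratio
tests against nested fits, mirroring an analysis-of-deviance layout:
random-intercept row, overall model, region, treatment, their
interaction, and per-treatment-level post hoc contrasts.

Cutpoints are optimized through the unconstrained parameterization
``theta_1 = zeta_1, theta_j = theta_{j-1} + exp(zeta_j)``, which keeps
them strictly ordered. Fits are deterministic: fixed starting values
(cumulative empirical logits, sigma start 0.3) and gradient tolerance
1e-8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logsumexp

# ---------------------------------------------------------------------------
# elementary statistics


def compute_sbs(bs_treatment: int, bs_control: int) -> int:
    """Standardized bleach score: treatment minus control, each in {1,2,3}."""
    for v in (bs_treatment, bs_control):
        if v not in (1, 2, 3):
            raise ValueError(f"bleaching score {v!r} not in {{1, 2, 3}}")
    return int(bs_treatment) - int(bs_control)


def proportion_bleached(sbs) -> float:
    """Fraction of scores with SBS > 0 (net bleaching relative to control)."""
    arr = np.asarray(sbs)
    if arr.size == 0:
        raise ValueError("empty SBS vector")
    return float((arr > 0).mean())


# ---------------------------------------------------------------------------
# proportional-odds machinery


class SeparationError(RuntimeError):
    """Raised when the ordinal MLE diverges (complete separation)."""


@dataclass
class CLMMFit:
    """A converged cumulative-link fit (``sigma_pop is None`` for fixed-only)."""

    cutpoints: np.ndarray
    beta: pd.Series
    sigma_pop: float | None
    loglik: float
    converged: bool
    n_obs: int
    categories: np.ndarray
    n_groups: int | None = None
    beta_se: pd.Series | None = None

    @property
    def n_params(self) -> int:
        return len(self.cutpoints) + len(self.beta) + (self.sigma_pop is not None)

    def category_probs(self, X: pd.DataFrame | None = None, u: float = 0.0) -> np.ndarray:
        """P(Y = k) for each row of X at random effect ``u``; rows sum to 1."""
        eta = np.zeros(1) if X is None else _as_matrix(X, list(self.beta.index)) @ self.beta.values
        cum = expit(np.subtract.outer(self.cutpoints, eta + u))        # (K-1, n)
        cum = np.vstack([np.zeros_like(cum[:1]), cum, np.ones_like(cum[:1])])
        return np.diff(cum, axis=0).T


def _as_matrix(X, names=None) -> np.ndarray:
    if X is None:
        return np.zeros((0, 0))
    if isinstance(X, pd.DataFrame):
        return X[names].to_numpy(float) if names else X.to_numpy(float)
    return np.asarray(X, float)


def _theta(zeta: np.ndarray) -> np.ndarray:
    th = np.empty_like(zeta)
    th[0] = zeta[0]
    if len(zeta) > 1:
        th[1:] = zeta[0] + np.cumsum(np.exp(zeta[1:]))
    return th


def _grad_theta_to_zeta(gtheta: np.ndarray, zeta: np.ndarray) -> np.ndarray:
    # theta_j depends on zeta_1 and exp(zeta_m) for m <= j
    rev_cum = np.cumsum(gtheta[::-1])[::-1]
    g = np.empty_like(gtheta)
    g[0] = rev_cum[0]
    if len(gtheta) > 1:
        g[1:] = np.exp(zeta[1:]) * rev_cum[1:]
    return g


def _logistic_parts(z):
    """(F, f, f') of the logistic CDF, honoring +/- inf."""
    F = expit(z)
    f = F * (1.0 - F)
    fp = f * (1.0 - 2.0 * F)
    return F, f, fp


def _obs_terms(theta, eta, k, K):
    """Per-observation (p, f_hi, f_lo, fp_hi, fp_lo) for categories k (0-based)."""
    z_hi = np.where(k < K - 1, theta[np.minimum(k, K - 2)] - eta, np.inf)
    z_lo = np.where(k > 0, theta[np.maximum(k - 1, 0)] - eta, -np.inf)
    F_hi, f_hi, fp_hi = _logistic_parts(z_hi)
    F_lo, f_lo, fp_lo = _logistic_parts(z_lo)
    p = np.clip(F_hi - F_lo, 1e-300, 1.0)
    return p, f_hi, f_lo, fp_hi, fp_lo


def _clm_nll_grad(params, Xm, k, K):
    """Negative log-likelihood and gradient in (zeta, beta)."""
    ncut = K - 1
    zeta, beta = params[:ncut], params[ncut:]
    theta = _theta(zeta)
    eta = Xm @ beta if Xm.size else np.zeros(len(k))
    p, f_hi, f_lo, _, _ = _obs_terms(theta, eta, k, K)
    nll = -np.log(p).sum()
    gtheta = np.zeros(ncut)
    w_hi = f_hi / p
    w_lo = f_lo / p
    sel = k < K - 1
    np.add.at(gtheta, k[sel], w_hi[sel])
    sel = k > 0
    np.add.at(gtheta, k[sel] - 1, -w_lo[sel])
    geta = w_lo - w_hi
    gbeta = Xm.T @ geta if Xm.size else np.zeros(0)
    grad = np.concatenate([_grad_theta_to_zeta(gtheta, zeta), gbeta])
    return nll, -grad


def _start_values(y_idx: np.ndarray, K: int, n_beta: int) -> np.ndarray:
    freq = np.bincount(y_idx, minlength=K) / len(y_idx)
    cum = np.clip(np.cumsum(freq)[:-1], 1e-3, 1 - 1e-3)
    theta0 = np.log(cum / (1 - cum))
    theta0 = np.maximum.accumulate(theta0 + 1e-6 * np.arange(K - 1))
    zeta0 = np.empty(K - 1)
    zeta0[0] = theta0[0]
    if K > 2:
        zeta0[1:] = np.log(np.maximum(np.diff(theta0), 1e-3))
    return np.concatenate([zeta0, np.zeros(n_beta)])


def _encode(y):
    cats = np.unique(np.asarray(y))
    if len(cats) < 2:
        raise ValueError("need >= 2 observed categories")
    idx = np.searchsorted(cats, np.asarray(y))
    return cats, idx


def _beta_names(X) -> list[str]:
    if X is None:
        return []
    if isinstance(X, pd.DataFrame):
        return list(X.columns)
    return [f"x{i + 1}" for i in range(np.asarray(X).shape[1])]


def _fd_hessian(fun, x, step=1e-4):
    n = len(x)
    H = np.empty((n, n))
    hs = step * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = hs[i]
            ej = np.zeros(n); ej[j] = hs[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej)
                - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * hs[i] * hs[j])
    return H


def fit_clm(y, X=None, compute_se: bool = True) -> CLMMFit:
    """Maximum-likelihood proportional-odds fit without random effects.

    ``X`` is the fixed-effect design (no intercept column; the cutpoints
    absorb the location). Raises :class:`SeparationError` when the MLE
    diverges, e.g. under complete separation.
    """
    cats, k = _encode(y)
    K = len(cats)
    names = _beta_names(X)
    Xm = _as_matrix(X, names if isinstance(X, pd.DataFrame) else None)
    if Xm.size and np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    x0 = _start_values(k, K, Xm.shape[1] if Xm.size else 0)
    res = optimize.minimize(_clm_nll_grad, x0, args=(Xm, k, K), jac=True,
                            method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 1000})
    ncut = K - 1
    beta = res.x[ncut:]
    if np.any(np.abs(beta) > 30):
        raise SeparationError(
            "fixed-effect estimate diverged (|beta| > 30); the data are "
            "likely completely separated")
    converged = bool(res.success or np.linalg.norm(res.jac, np.inf) < 1e-5)
    se = None
    if compute_se and converged:
        H = _fd_hessian(lambda p: _clm_nll_grad(p, Xm, k, K)[0], res.x)
        try:
            cov = np.linalg.inv(H)
            se = pd.Series(np.sqrt(np.clip(np.diag(cov)[ncut:], 0, None)), index=names)
        except np.linalg.LinAlgError:
            se = None
    return CLMMFit(cutpoints=_theta(res.x[:ncut]),
                   beta=pd.Series(beta, index=names),
                   sigma_pop=None, loglik=-res.fun, converged=converged,
                   n_obs=len(k), categories=cats, beta_se=se)


# ---------------------------------------------------------------------------
# mixed model: adaptive Gauss-Hermite quadrature


def _gh_nodes(n: int):
    # physicists' Hermite nodes/weights for integrals against exp(-x^2)
    return np.polynomial.hermite.hermgauss(n)


def _group_logprob_derivs(theta, eta, k, K, u, gidx, n_groups):
    """Sum over each group of (logp, dlogp/du, d2logp/du2) at offsets u[g]."""
    p, f_hi, f_lo, fp_hi, fp_lo = _obs_terms(theta, eta + u[gidx], k, K)
    dp = f_lo - f_hi           # d p / du
    d2p = fp_hi - fp_lo        # d^2 p / du^2
    dlog = dp / p
    d2log = d2p / p - dlog ** 2
    return (np.bincount(gidx, np.log(p), n_groups),
            np.bincount(gidx, dlog, n_groups),
            np.bincount(gidx, d2log, n_groups))


def _conditional_modes(theta, eta, k, K, gidx, n_groups, sigma, u0=None):
    """Newton maximization of each group's integrand log-density in u."""
    u = np.zeros(n_groups) if u0 is None else u0.copy()
    inv_var = 1.0 / sigma ** 2
    for _ in range(60):
        _, d1, d2 = _group_logprob_derivs(theta, eta, k, K, u, gidx, n_groups)
        g = d1 - u * inv_var
        h = d2 - inv_var          # strictly negative: log-concave integrand
        step = np.clip(g / h, -5.0, 5.0)
        u = u - step
        if np.max(np.abs(g)) < 1e-10:
            break
    _, _, d2 = _group_logprob_derivs(theta, eta, k, K, u, gidx, n_groups)
    curv = -(d2 - inv_var)
    return u, curv


def _clmm_nll(params, Xm, k, K, gidx, n_groups, nodes, weights, mode_cache):
    ncut = K - 1
    zeta = params[:ncut]
    beta = params[ncut:-1]
    sigma = np.exp(params[-1])
    theta = _theta(zeta)
    eta = Xm @ beta if Xm.size else np.zeros(len(k))
    u_hat, curv = _conditional_modes(theta, eta, k, K, gidx, n_groups, sigma,
                                     u0=mode_cache.get("u"))
    mode_cache["u"] = u_hat
    scale = 1.0 / np.sqrt(curv)                       # (n_groups,)
    # adaptive GH: u = u_hat + sqrt(2) * scale * x_node
    log_terms = np.empty((len(nodes), n_groups))
    log_norm = -0.5 * np.log(2 * np.pi) - np.log(sigma)
    for j, (x, w) in enumerate(zip(nodes, weights)):
        u = u_hat + np.sqrt(2.0) * scale * x
        lp, _, _ = _group_logprob_derivs(theta, eta, k, K, u, gidx, n_groups)
        log_prior = log_norm - 0.5 * (u / sigma) ** 2
        log_terms[j] = np.log(w) + x ** 2 + lp + log_prior
    log_lik_g = 0.5 * np.log(2.0) + np.log(scale) + logsumexp(log_terms, axis=0)
    return -log_lik_g.sum()


def fit_clmm(y, X, groups, n_nodes: int = 15, compute_se: bool = False) -> CLMMFit:
    """Proportional-odds fit with a normal random intercept per group.

    The marginal likelihood integrates the intercept by adaptive
    Gauss-Hermite quadrature with ``n_nodes`` nodes (centered at each
    group's conditional mode and scaled by its curvature, so the default
    15 nodes are accurate even for large groups).
    """
    cats, k = _encode(y)
    K = len(cats)
    names = _beta_names(X)
    Xm = _as_matrix(X, names if isinstance(X, pd.DataFrame) else None)
    codes, uniques = pd.factorize(np.asarray(groups))
    n_groups = len(uniques)
    if n_groups < 2:
        raise ValueError("need >= 2 groups to estimate a random intercept")
    nodes, weights = _gh_nodes(n_nodes)
    start = fit_clm(y, X, compute_se=False)
    ncut = K - 1
    zeta0 = np.empty(ncut)
    zeta0[0] = start.cutpoints[0]
    if ncut > 1:
        zeta0[1:] = np.log(np.maximum(np.diff(start.cutpoints), 1e-6))
    x0 = np.concatenate([zeta0, start.beta.values, [np.log(0.3)]])
    cache: dict = {}
    nll = lambda p: _clmm_nll(p, Xm, k, K, codes, n_groups, nodes, weights, cache)  # noqa: E731
    bounds = [(None, None)] * (len(x0) - 1) + [(np.log(1e-4), np.log(50.0))]
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500})
    beta = res.x[ncut:-1]
    sigma = float(np.exp(res.x[-1]))
    converged = bool(res.success)
    if np.any(np.abs(beta) > 30):
        raise SeparationError("fixed-effect estimate diverged (|beta| > 30)")
    se = None
    if compute_se and converged:
        H = _fd_hessian(nll, res.x)
        try:
            cov = np.linalg.inv(H)
            se = pd.Series(np.sqrt(np.clip(np.diag(cov)[ncut:-1], 0, None)), index=names)
        except np.linalg.LinAlgError:
            se = None
    return CLMMFit(cutpoints=_theta(res.x[:ncut]),
                   beta=pd.Series(beta, index=names), sigma_pop=sigma,
                   loglik=-res.fun, converged=converged, n_obs=len(k),
                   categories=cats, n_groups=n_groups, beta_se=se)


def lrt(null_fit: CLMMFit, full_fit: CLMMFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested converged fits: (statistic, df, p)."""
    if not (null_fit.converged and full_fit.converged):
        raise RuntimeError("both fits must have converged")
    df = full_fit.n_params - null_fit.n_params
    if df < 1:
        raise ValueError("models are not nested (df < 1)")
    stat = max(0.0, 2.0 * (full_fit.loglik - null_fit.loglik))
    return stat, df, float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# analysis-of-deviance batteries


@dataclass
class DevianceTable:
    """LRT rows plus group sample sizes; ``to_frame`` gives the CSV layout."""

    rows: list[dict] = field(default_factory=list)
    sample_sizes: dict[str, tuple[int, int]] = field(default_factory=dict)  # group -> (thalli, pops)

    def add(self, term: str, df=None, stat=None, p=None, note: str = "") -> None:
        self.rows.append({"term": term, "df": df, "lr_stat": stat, "p": p, "note": note})

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.rows)
        for grp, (n_th, n_pop) in self.sample_sizes.items():
            out.attrs[grp] = f"{n_th} ({n_pop})"
        return out

    def p_of(self, term: str):
        for r in self.rows:
            if r["term"] == term:
                return r["p"]
        raise KeyError(term)


def _region_indicator(df: pd.DataFrame, native_label: str) -> pd.Series:
    return (df["range_class"] != native_label).astype(float).rename("region")


def _treatment_design(df: pd.DataFrame, with_region: bool, with_interaction: bool,
                      native_label: str) -> pd.DataFrame:
    levels = list(pd.unique(df["level"]))
    X = pd.DataFrame(index=df.index)
    if with_region:
        X["region"] = _region_indicator(df, native_label)
    for lvl in levels[1:]:
        X[f"level[{lvl}]"] = (df["level"] == lvl).astype(float)
    if with_interaction and with_region:
        for lvl in levels[1:]:
            X[f"region:level[{lvl}]"] = X["region"] * X[f"level[{lvl}]"]
    return X


def deviance_table(assays: pd.DataFrame, stressor: str, stage: str = "field",
                   native_label: str = "native_source",
                   coastlines=None, n_nodes: int = 15) -> DevianceTable:
    """Region x treatment analysis-of-deviance for one stressor and stage.

    Rows: random-intercept test (fixed-only vs mixed full model), overall
    model, then region, treatment and interaction each dropped from the
    full model, plus per-level post hoc region contrasts. ``coastlines``
    restricts the non-native side to given coastline codes (native-source
    populations are always included).
    """
    df = assays[(assays["stressor"] == stressor) & (assays["stage"] == stage)].copy()
    # the contrast is native *source* vs non-native: other native
    # populations do not share the invasion's evolutionary history
    df = df[(df["range_class"] == native_label) | (df["range_class"] == "invaded")]
    if coastlines is not None:
        keep = (df["range_class"] == native_label) | df["coastline"].isin(coastlines)
        df = df[keep]
    if df["level"].nunique() < 2:
        raise ValueError("need >= 2 treatment levels")
    tab = DevianceTable()
    for grp_name, sub in (("native", df[df.range_class == native_label]),
                          ("nonnative", df[df.range_class != native_label])):
        tab.sample_sizes[grp_name] = (sub["thallus"].nunique(), sub["population"].nunique())
    y = df["sbs"].to_numpy()
    pops_per_region = df.groupby(_region_indicator(df, native_label))["population"].nunique()
    mixed_ok = df["population"].nunique() >= 2 and (pops_per_region >= 2).all()

    X_full = _treatment_design(df, True, True, native_label)
    fitter = (lambda X: fit_clmm(y, X, df["population"], n_nodes)) if mixed_ok \
        else (lambda X: fit_clm(y, X, compute_se=False))
    full = fitter(X_full)
    if mixed_ok:
        clm_full = fit_clm(y, X_full, compute_se=False)
        stat, dfree, p = lrt(clm_full, full)
        tab.add("(1 | population)", dfree, stat, p)
    else:
        tab.add("(1 | population)", note="not estimable: a region has a single population")
    null = fitter(None)
    stat, dfree, p = lrt(null, full)
    tab.add("overall", dfree, stat, p)
    for term, keep_cols in (
        ("region", [c for c in X_full if c != "region"]),
        ("treatment", [c for c in X_full if not c.startswith("level")]),
        ("interaction", [c for c in X_full if ":" not in c]),
    ):
        reduced = fitter(X_full[keep_cols])
        stat, dfree, p = lrt(reduced, full)
        tab.add(term, dfree, stat, p)
    # post hoc: region effect within each treatment level
    for lvl in pd.unique(df["level"]):
        sub = df[df["level"] == lvl]
        ysub = sub["sbs"].to_numpy()
        Xr = pd.DataFrame({"region": _region_indicator(sub, native_label)})
        try:
            sub_mixed = mixed_ok and sub["population"].nunique() >= 2
            if sub_mixed:
                f1 = fit_clmm(ysub, Xr, sub["population"], n_nodes)
                f0 = fit_clmm(ysub, None, sub["population"], n_nodes)
            else:
                f1 = fit_clm(ysub, Xr, compute_se=False)
                f0 = fit_clm(ysub, None, compute_se=False)
            stat, dfree, p = lrt(f0, f1)
            tab.add(f"post hoc {lvl}", dfree, stat, p)
        except (ValueError, RuntimeError) as exc:
            tab.add(f"post hoc {lvl}", note=f"not estimable: {exc}")
    return tab


def ove_contrast(assays: pd.DataFrame, niche_labels: pd.DataFrame,
                 exclude=(), level=None, n_nodes: int = 15):
    """Overlap-vs-Expansion phenotype contrast.

    Populations labeled O or E (from the niche classification) are compared
    on SBS with a population random intercept; returns
    ``(fit, p, group mean SBS)``. ``exclude`` removes populations whose
    source assignment is ambiguous; ``level`` optionally restricts to one
    treatment level.
    """
    lab = niche_labels[["population", "label"]]
    df = assays.merge(lab, on="population")
    df = df[df["label"].isin(["O", "E"]) & ~df["population"].isin(set(exclude))]
    if level is not None:
        df = df[df["level"] == level]
    n_by = df.groupby("label")["population"].nunique()
    if n_by.get("O", 0) == 0 or n_by.get("E", 0) == 0:
        raise ValueError("need populations in both O and E after exclusions")
    y = df["sbs"].to_numpy()
    X = pd.DataFrame({"E": (df["label"] == "E").astype(float).values}, index=df.index)
    if df["population"].nunique() >= 2:
        f1 = fit_clmm(y, X, df["population"], n_nodes)
        f0 = fit_clmm(y, None, df["population"], n_nodes)
    else:
        f1 = fit_clm(y, X, compute_se=False)
        f0 = fit_clm(y, None, compute_se=False)
    _, _, p = lrt(f0, f1)
    means = df.groupby("label")["sbs"].mean().to_dict()
    return f1, float(p), means


def cline_model(assays: pd.DataFrame, pop_info: pd.DataFrame, level: str,
                native_label: str = "native_source", n_nodes: int = 15) -> dict:
    """SST cline in stress tolerance: SBS ~ SST + region + SST:region + (1|pop).

    ``pop_info`` needs columns ``population, sstmax`` plus optionally
    ``lat`` and ``coastline`` for the SSTmax-vs-|latitude| R^2 diagnostic.
    Returns the fit, deviance rows, per-region predicted bleaching
    probability curves over the observed SST range, and the diagnostic.
    """
    df = assays[assays["level"] == level].merge(
        pop_info[["population", "sstmax"]], on="population")
    if len(df) == 0:
        raise ValueError(f"no assays at level {level!r}")
    # whole native coastline (source + nonsource) vs the invaded range:
    # the native cline spans both source and nonsource latitudes
    region = (df["range_class"] == "invaded").astype(float).rename("region")
    sst_mean = df["sstmax"].mean()
    sst_c = (df["sstmax"] - sst_mean).rename("sst")
    if df.groupby(region)["sstmax"].std().fillna(0.0).max() == 0:
        raise ValueError("SST constant within both regions: slope not estimable")
    X_full = pd.DataFrame({"sst": sst_c, "region": region,
                           "sst:region": sst_c * region})
    y = df["sbs"].to_numpy()
    mixed_ok = df["population"].nunique() >= 2
    fitter = (lambda X: fit_clmm(y, X, df["population"], n_nodes,
                                 compute_se=X is X_full)) if mixed_ok \
        else (lambda X: fit_clm(y, X, compute_se=X is X_full))
    full = fitter(X_full)
    tab = DevianceTable()
    if mixed_ok:
        stat, dfree, p = lrt(fit_clm(y, X_full, compute_se=False), full)
        tab.add("(1 | population)", dfree, stat, p)
    else:
        tab.add("(1 | population)", note="not estimable: single population")
    stat, dfree, p = lrt(fitter(None), full)
    tab.add("overall", dfree, stat, p)
    for term in ("region", "sst", "sst:region"):
        reduced = fitter(X_full[[c for c in X_full if c != term]])
        stat, dfree, p = lrt(reduced, full)
        tab.add(term, dfree, stat, p)
    for grp_name, sub in (("native", df[region == 0]), ("nonnative", df[region == 1])):
        tab.sample_sizes[grp_name] = (sub["thallus"].nunique(), sub["population"].nunique())

    sst_grid = np.linspace(df["sstmax"].min(), df["sstmax"].max(), 50)
    curves = []
    for reg in (0.0, 1.0):
        Xp = pd.DataFrame({"sst": sst_grid - sst_mean,
                           "region": np.full_like(sst_grid, reg),
                           "sst:region": (sst_grid - sst_mean) * reg})
        probs = full.category_probs(Xp)
        bleach = probs[:, full.categories > 0].sum(axis=1)
        curves.append(pd.DataFrame({"sstmax": sst_grid, "region": reg,
                                    "p_bleached": bleach}))
    out = {"fit": full, "rows": tab, "curves": pd.concat(curves, ignore_index=True),
           "sst_mean": sst_mean}
    if {"lat", "coastline"} <= set(pop_info.columns):
        out["sst_lat_r2"] = sst_latitude_r2(pop_info)
    return out


def sst_latitude_r2(pop_info: pd.DataFrame) -> dict[str, float]:
    """R^2 of SSTmax against |latitude| per coastline (cline diagnostic)."""
    out = {}
    for coast, sub in pop_info.groupby("coastline"):
        if len(sub) < 3 or sub["sstmax"].std() == 0:
            continue
        r = stats.pearsonr(np.abs(sub["lat"]), sub["sstmax"])[0]
        out[str(coast)] = float(r ** 2)
    return out
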