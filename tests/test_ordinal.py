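import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.special import expit

from nicheshift import ordinal
from nicheshift.synthetic_world import (PhenoSimParams, WorldConfig, draw_bs,
                                        make_phenotypes, make_world)


class TestElementary:
    @pytest.mark.parametrize("trt,ctrl,expected",
                             [(3, 1, 2), (2, 2, 0), (1, 3, -2), (2, 1, 1)])
    def test_sbs_difference(self, trt, ctrl, expected):
        assert ordinal.compute_sbs(trt, ctrl) == expected

    def test_sbs_rejects_out_of_range_scores(self):
        with pytest.raises(ValueError):
            ordinal.compute_sbs(4, 1)
        with pytest.raises(ValueError):
            ordinal.compute_sbs(2, 0)

    def test_proportion_bleached(self):
        assert ordinal.proportion_bleached([0, 0, 0]) == 0.0
        assert ordinal.proportion_bleached([2, 0, 1, 0]) == 0.5
        assert ordinal.proportion_bleached([2, 2]) == 1.0
        with pytest.raises(ValueError):
            ordinal.proportion_bleached([])


class TestFitCLM:
    def test_balanced_identical_groups_give_zero_coefficient(self):
        y = np.tile([1, 1, 2, 2, 3], 20)
        x = np.repeat([0.0, 1.0], 50)
        fit = ordinal.fit_clm(y, pd.DataFrame({"g": x}))
        assert abs(fit.beta["g"]) < 1e-6

    def test_binary_outcome_equals_logistic_regression(self):
        """With K = 2 the proportional-odds model is logistic regression:
        P(Y=2|x) = expit(x*beta - theta1)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        x = rng.normal(size=400)
        y = draw_bs(0.8 * x, (0.3,), rng)
        fit = ordinal.fit_clm(y, pd.DataFrame({"x": x}))
        oracle = sm.Logit((y == 2).astype(int), sm.add_constant(x)).fit(disp=False)
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-6)
        assert fit.beta["x"] == pytest.approx(np.asarray(oracle.params)[1], abs=1e-5)
        assert fit.cutpoints[0] == pytest.approx(-np.asarray(oracle.params)[0],
                                                 abs=1e-5)

    def test_matches_statsmodels_ordered_model(self):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        rng = np.random.default_rng(3)
        x = rng.normal(size=600)
        y = draw_bs(1.2 * x, (0.5, 1.5), rng)
        fit = ordinal.fit_clm(y, pd.DataFrame({"x": x}))
        oracle = OrderedModel(y, x[:, None], distr="logit").fit(
            method="bfgs", disp=False)
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-5)
        assert fit.beta["x"] == pytest.approx(np.asarray(oracle.params)[0], abs=1e-4)

    def test_simulation_recovery_within_three_se(self):
        rng = np.random.default_rng(4)
        theta = np.array([-0.5, 1.0])
        beta = 1.0
        x = rng.normal(size=5000)
        y = draw_bs(beta * x, theta, rng)
        fit = ordinal.fit_clm(y, pd.DataFrame({"x": x}))
        assert abs(fit.beta["x"] - beta) < 3 * fit.beta_se["x"]

    def test_category_probabilities_sum_to_one(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=300)
        y = draw_bs(0.5 * x, (0.0, 1.0), rng)
        fit = ordinal.fit_clm(y, pd.DataFrame({"x": x}))
        probs = fit.category_probs(pd.DataFrame({"x": np.linspace(-3, 3, 7)}))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-10)
        assert (probs >= 0).all()

    def test_complete_separation_raises(self):
        y = np.repeat([1, 3], 30)
        x = np.repeat([0.0, 1.0], 30)
        with pytest.raises(ordinal.SeparationError):
            ordinal.fit_clm(y, pd.DataFrame({"x": x}))

    def test_single_category_rejected(self):
        with pytest.raises(ValueError, match="2 observed categories"):
            ordinal.fit_clm(np.ones(10), None)


def _clustered_data(seed, n_groups=20, per_group=50, beta=1.0, sigma=0.7,
                    theta=(0.0, 1.5)):
    rng = np.random.default_rng(seed)
    groups = np.repeat(np.arange(n_groups), per_group)
    u = rng.normal(0, sigma, n_groups) if sigma > 0 else np.zeros(n_groups)
    x = rng.normal(size=n_groups * per_group)
    y = draw_bs(beta * x + u[groups], theta, rng)
    return y, pd.DataFrame({"x": x}), groups


class TestFitCLMM:
    def test_sigma_zero_limit_collapses_to_clm(self):
        y, X, groups = _clustered_data(seed=0, n_groups=20, per_group=100,
                                       sigma=0.0)
        mixed = ordinal.fit_clmm(y, X, groups)
        fixed = ordinal.fit_clm(y, X)
        assert mixed.sigma_pop < 0.05
        assert abs(mixed.loglik - fixed.loglik) < 0.01

    def test_quadrature_node_count_stability(self):
        y, X, groups = _clustered_data(seed=1)
        f15 = ordinal.fit_clmm(y, X, groups, n_nodes=15)
        f25 = ordinal.fit_clmm(y, X, groups, n_nodes=25)
        assert abs(f15.loglik - f25.loglik) < 1e-4

    def test_observation_order_invariance(self):
        y, X, groups = _clustered_data(seed=2, n_groups=8, per_group=30)
        fit = ordinal.fit_clmm(y, X, groups)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(y))
        fit_p = ordinal.fit_clmm(y[perm], X.iloc[perm].reset_index(drop=True),
                                 groups[perm])
        assert fit.loglik == pytest.approx(fit_p.loglik, abs=1e-6)

    def test_parameter_recovery_over_replicates(self):
        betas, sigmas = [], []
        for rep in range(12):
            y, X, groups = _clustered_data(seed=100 + rep)
            fit = ordinal.fit_clmm(y, X, groups)
            betas.append(fit.beta["x"])
            sigmas.append(fit.sigma_pop)
        assert abs(np.mean(betas) - 1.0) < 0.1
        assert abs(np.mean(sigmas) - 0.7) < 0.15

    def test_single_group_rejected(self):
        y = np.tile([1, 2, 3], 10)
        with pytest.raises(ValueError, match="2 groups"):
            ordinal.fit_clmm(y, None, np.zeros(30))


def _independent_nll(params, y, x, K):
    """Proportional-odds likelihood written from scratch for the oracle."""
    theta = np.sort(params[:K - 1])
    beta = params[K - 1]
    eta = beta * x
    ll = 0.0
    for yi, ei in zip(y, eta):
        hi = 1.0 if yi == K else expit(theta[yi - 1] - ei)
        lo = 0.0 if yi == 1 else expit(theta[yi - 2] - ei)
        ll += np.log(max(hi - lo, 1e-300))
    return -ll


class TestLRT:
    def test_identical_models_give_zero_statistic(self):
        y = np.tile([1, 2, 3], 30)
        fit = ordinal.fit_clm(y, None)
        big = ordinal.fit_clm(y, pd.DataFrame({"x": np.zeros(90) +
                                               np.tile([0, 1, 0], 30)}))
        stat, df, p = ordinal.lrt(fit, big)
        assert stat == pytest.approx(0.0, abs=1e-6)
        assert df == 1
        assert p == pytest.approx(1.0, abs=1e-4)

    def test_non_nested_rejected(self):
        y = np.tile([1, 2, 3], 30)
        x = pd.DataFrame({"x": np.random.default_rng(0).normal(size=90)})
        small = ordinal.fit_clm(y, None)
        big = ordinal.fit_clm(y, x)
        with pytest.raises(ValueError, match="nested"):
            ordinal.lrt(big, small)

    def test_statistic_matches_from_scratch_mle_oracle(self):
        """LRT statistic against an independent Nelder-Mead maximization
        of a likelihood written directly from the model definition."""
        rng = np.random.default_rng(11)
        x = np.repeat([0.0, 1.0], 40)
        y = draw_bs(0.9 * x, (0.2, 1.2), rng)
        K = 3
        full = ordinal.fit_clm(y, pd.DataFrame({"x": x}))
        null = ordinal.fit_clm(y, None)
        stat, _, _ = ordinal.lrt(null, full)

        res_full = optimize.minimize(
            _independent_nll, x0=[0.0, 1.0, 0.0], args=(y, x, K),
            method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12,
                                           "maxiter": 20000})
        res_null = optimize.minimize(
            lambda p: _independent_nll(np.append(p, 0.0), y, x, K),
            x0=[0.0, 1.0], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        oracle_stat = 2 * (res_null.fun - res_full.fun)
        assert stat == pytest.approx(oracle_stat, abs=1e-4)


def _assay_world(seed=30):
    return make_world(WorldConfig(seed=seed, n_native_pops=8, n_source_pops=4,
                                  n_invaded_pops=8))


class TestDevianceTable:
    def test_planted_interaction_detected_at_top_level_only(self):
        """An effect present only at the highest severity should light up
        the interaction row and the top-level post hoc contrast."""
        world = _assay_world()
        rng = np.random.default_rng(40)
        rows = []
        sev = {"1hr": 0.5, "2hr": 1.5, "4hr": 3.0}
        for pop_row in world.occurrences.itertuples():
            invaded = pop_row.range_class == "invaded"
            u = rng.normal(0, 0.3)
            for t in range(14):
                ctrl = int(draw_bs(np.array([u]), (2.2, 4.0), rng)[0])
                for lvl, s in sev.items():
                    eta = s + u - 1.5 * invaded * (lvl == "4hr")
                    bs = int(draw_bs(np.array([eta]), (2.2, 4.0), rng)[0])
                    rows.append([f"{pop_row.population}-t{t}", pop_row.population,
                                 pop_row.coastline, pop_row.range_class,
                                 "heat40", lvl, "field", ctrl, bs, bs - ctrl])
        assays = pd.DataFrame(rows, columns=["thallus", "population", "coastline",
                                             "range_class", "stressor", "level",
                                             "stage", "bs_control",
                                             "bs_treatment", "sbs"])
        tab = ordinal.deviance_table(assays, "heat40")
        assert tab.p_of("interaction") < 0.05
        assert tab.p_of("post hoc 4hr") < 0.05
        assert tab.p_of("post hoc 1hr") > 0.05
        assert tab.sample_sizes["native"][1] == 4

    def test_single_population_region_marks_random_row_not_estimable(self):
        world = _assay_world()
        params = PhenoSimParams(thalli_per_pop=10)
        assays = make_phenotypes(world, params, seed=1, stressors=("heat40",))
        one_native = assays[(assays.range_class == "invaded")
                            | (assays.population == "p001")]
        tab = ordinal.deviance_table(one_native, "heat40")
        rand = [r for r in tab.rows if r["term"] == "(1 | population)"][0]
        assert rand["p"] is None and "not estimable" in rand["note"]
        assert tab.p_of("treatment") is not None

    def test_requires_multiple_levels(self):
        world = _assay_world()
        assays = make_phenotypes(world, PhenoSimParams(thalli_per_pop=4),
                                 seed=2, stressors=("heat40",))
        with pytest.raises(ValueError, match="2 treatment levels"):
            ordinal.deviance_table(assays[assays.level == "1hr"], "heat40")


class TestOvEContrast:
    def _assays_with_labels(self, e_advantage, seed=50):
        world = _assay_world(seed)
        occ = world.occurrences
        inv_pops = occ[occ.range_class == "invaded"].population.tolist()
        e_pops = inv_pops[:4]
        labels = pd.DataFrame({
            "population": occ.population,
            "label": ["E" if p in e_pops else "O" for p in occ.population],
        })
        effects = {p: -e_advantage for p in e_pops}
        assays = make_phenotypes(world, PhenoSimParams(beta_region=0.0,
                                                       beta_sst=0.0,
                                                       sigma_pop=0.3,
                                                       thalli_per_pop=14),
                                 seed=seed, stressors=("heat40",),
                                 pop_effects=effects)
        return assays, labels, e_pops

    def test_planted_expansion_advantage_detected(self):
        assays, labels, _ = self._assays_with_labels(e_advantage=2.0)
        fit, p, means = ordinal.ove_contrast(assays, labels, level="4hr")
        assert means["E"] < means["O"]
        assert p < 0.05
        assert fit.beta["E"] < 0

    def test_exclusions_removed_from_fit(self):
        assays, labels, e_pops = self._assays_with_labels(e_advantage=0.0)
        excluded = e_pops[:1]
        fit, _, _ = ordinal.ove_contrast(assays, labels, exclude=excluded)
        merged = assays.merge(labels, on="population")
        kept = merged[merged.label.isin(["O", "E"])
                      & ~merged.population.isin(excluded)]
        assert fit.n_obs == len(kept)

    def test_empty_group_rejected(self):
        assays, labels, _ = self._assays_with_labels(e_advantage=0.0)
        labels_all_o = labels.assign(label="O")
        with pytest.raises(ValueError, match="both O and E"):
            ordinal.ove_contrast(assays, labels_all_o)


class TestClineModel:
    def _pop_info(self, world):
        occ = world.occurrences
        info = occ[["population", "lat", "coastline", "range_class"]].copy()
        info["sstmax"] = [world.env.value_at("SSTmax", r.lon, r.lat)
                          for r in occ.itertuples()]
        return info

    def test_parallel_clines_with_region_offset(self):
        """Planted equal slopes and a region offset: interaction null,
        region significant, slope sign recovered."""
        world = _assay_world(seed=31)
        params = PhenoSimParams(beta_region=-1.5, beta_sst=-0.3, sigma_pop=0.3,
                                thalli_per_pop=16)
        assays = make_phenotypes(world, params, seed=3, stressors=("heat40",))
        out = ordinal.cline_model(assays, self._pop_info(world), level="4hr")
        assert out["rows"].p_of("sst:region") > 0.05
        assert out["rows"].p_of("region") < 0.05
        assert out["fit"].beta["sst"] < 0
        assert set(out["sst_lat_r2"]) == {"native", "invaded"}

    def test_zero_slope_not_significant(self):
        hits = 0
        for rep in range(5):
            world = _assay_world(seed=60 + rep)
            params = PhenoSimParams(beta_region=-1.0, beta_sst=0.0,
                                    sigma_pop=0.4, thalli_per_pop=10)
            assays = make_phenotypes(world, params, seed=rep,
                                     stressors=("heat40",))
            out = ordinal.cline_model(assays, self._pop_info(world), level="4hr")
            fit = out["fit"]
            z = fit.beta["sst"] / fit.beta_se["sst"]
            hits += abs(z) < 2
        assert hits >= 4

    def test_duplicated_regions_give_zero_region_effect(self):
        world = _assay_world(seed=32)
        params = PhenoSimParams(beta_region=0.0, beta_sst=-0.2, sigma_pop=0.0,
                                thalli_per_pop=12)
        assays = make_phenotypes(world, params, seed=4, stressors=("heat40",))
        nat = assays[assays.range_class != "invaded"]
        mirror = nat.copy()
        mirror["range_class"] = "invaded"
        mirror["population"] = mirror["population"] + "_m"
        mirror["thallus"] = mirror["thallus"] + "_m"
        both = pd.concat([nat, mirror], ignore_index=True)
        world_info = self._pop_info(world)
        info_m = world_info.copy()
        info_m["population"] = info_m["population"] + "_m"
        info = pd.concat([world_info, info_m], ignore_index=True)
        out = ordinal.cline_model(both, info, level="4hr")
        assert abs(out["fit"].beta["region"]) < 0.3
        assert out["rows"].p_of("region") > 0.05

    def test_prediction_curves_are_probabilities(self):
        world = _assay_world(seed=33)
        assays = make_phenotypes(world, PhenoSimParams(thalli_per_pop=8),
                                 seed=5, stressors=("heat40",))
        out = ordinal.cline_model(assays, self._pop_info(world), level="4hr")
        curves = out["curves"]
        assert curves.p_bleached.between(0, 1).all()
        assert set(curves.region) == {0.0, 1.0}

    def test_constant_sst_rejected(self):
        world = _assay_world(seed=34)
        assays = make_phenotypes(world, PhenoSimParams(thalli_per_pop=4),
                                 seed=6, stressors=("heat40",))
        info = self._pop_info(world)
        info["sstmax"] = 20.0
        with pytest.raises(ValueError, match="constant"):
            ordinal.cline_model(assays, info, level="4hr")
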