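import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from modaccess.models import (
    ModelSpec,
    MultilevelCountModel,
    fit_count_glmm,
    overdispersion_decision,
    stratified_analysis,
    urban_rural_stratum,
)
from modaccess.spatial import ZoneAdjacency


def simulate_counts(seed, n=200, n_groups=8, sigma=0.3, family="poisson",
                    alpha=0.2, true_rr=(1.0, 1.2, 1.4, 1.6, 1.8), base_rate=5.0 / 750):
    rng = np.random.default_rng(seed)
    q = rng.integers(1, 6, n)
    la = rng.integers(0, n_groups, n)
    b = rng.normal(0.0, sigma, n_groups)
    pop = rng.integers(500, 1001, n)
    mu = base_rate * pop * np.asarray(true_rr)[q - 1] * np.exp(b[la])
    if family == "poisson":
        y = rng.poisson(mu)
    else:
        r = 1.0 / alpha
        y = rng.negative_binomial(r, r / (r + mu))
    return pd.DataFrame(
        {"zone_id": [f"z{i}" for i in range(n)], "count": y, "quintile": q,
         "population": pop, "la_id": [f"LA{g}" for g in la]}
    )


@pytest.mark.parametrize("urc,stratum", [(1, "urban"), (2, "urban"), (3, "small town"),
                                         (4, "small town"), (5, "rural"), (6, "rural")])
def test_sixfold_collapse(urc, stratum):
    assert urban_rural_stratum(urc) == stratum


def test_sixfold_collapse_rejects_out_of_range():
    with pytest.raises(ValueError):
        urban_rural_stratum(7)


class TestMultilevelCountModel:
    def test_baseline_quintile_rr_is_one(self):
        df = simulate_counts(0)
        res = MultilevelCountModel.from_dataframe(df, "count", "la_id").fit()
        rr = res.rate_ratios()
        q1 = rr[rr["quintile"] == 1].iloc[0]
        assert q1["rr"] == 1.0 and q1["ci_low"] == 1.0 and q1["ci_high"] == 1.0
        assert bool(q1["baseline"])

    def test_confidence_level_uses_0995_normal_point(self):
        """99% Wald interval width is exactly 2 * z_{0.995} * SE."""
        df = simulate_counts(1)
        res = MultilevelCountModel.from_dataframe(
            df, "count", "la_id", family="poisson"
        ).fit()
        ci = res.conf_int(0.99)
        width = ci["upper"] - ci["lower"]
        assert np.allclose(width, 2.0 * norm.ppf(0.995) * res.bse, rtol=1e-10)

    def test_zero_variance_limit_matches_single_level_glm(self):
        """With no cluster heterogeneity the multilevel fit reduces to the
        ordinary single-level Poisson regression."""
        import statsmodels.api as sm

        df = simulate_counts(2, n=400, sigma=0.0, family="poisson")
        model = MultilevelCountModel.from_dataframe(
            df, "count", "la_id", family="poisson"
        )
        res = model.fit()
        glm = sm.GLM(
            model.endog, model.exog, family=sm.families.Poisson(), offset=model.offset
        ).fit()
        assert res.sigma_re < 0.1
        assert np.allclose(res.params.to_numpy(), glm.params, atol=1e-3)

    def test_recovers_rate_ratios_roughly(self):
        errs = []
        for seed in range(5):
            df = simulate_counts(100 + seed, family="poisson")
            res = MultilevelCountModel.from_dataframe(
                df, "count", "la_id", family="poisson"
            ).fit()
            rr = res.rate_ratios().set_index("quintile")["rr"]
            truth = {2: 1.2, 3: 1.4, 4: 1.6, 5: 1.8}
            errs += [abs(rr[q] - t) / t for q, t in truth.items()]
        assert np.mean(errs) < 0.15

    def test_random_intercept_variance_recovered(self):
        df = simulate_counts(3, n=600, n_groups=12, sigma=0.5)
        res = MultilevelCountModel.from_dataframe(
            df, "count", "la_id", family="poisson"
        ).fit()
        assert 0.2 < res.sigma_re < 0.9

    def test_input_validation(self):
        with pytest.raises(ValueError):
            MultilevelCountModel([1.5], [[1.0]], ["a"])  # non-integer counts
        with pytest.raises(ValueError):
            MultilevelCountModel([1], [[1.0]], ["a"], family="gamma")

    def test_summary_smoke(self):
        df = simulate_counts(4)
        res = MultilevelCountModel.from_dataframe(df, "count", "la_id").fit()
        text = res.summary()
        assert "random intercept" in text and "Q5" in text


class TestOverdispersionDecision:
    def test_equidispersed_chooses_poisson(self):
        d = overdispersion_decision(
            simulate_counts(10, family="poisson"), "count", "la_id", quad_points=5
        )
        assert d.family == "poisson"

    def test_overdispersed_chooses_negbin(self):
        d = overdispersion_decision(
            simulate_counts(11, family="negbin", alpha=1.0), "count", "la_id",
            quad_points=5,
        )
        assert d.family == "negbin"
        assert d.pearson_dispersion > 1
        assert d.lr_pvalue < 0.05

    def test_deterministic(self):
        df = simulate_counts(12, family="negbin", alpha=0.5)
        d1 = overdispersion_decision(df, "count", "la_id", quad_points=5)
        d2 = overdispersion_decision(df, "count", "la_id", quad_points=5)
        assert (d1.family, d1.pearson_dispersion) == (d2.family, d2.pearson_dispersion)


def grid_adjacency(ids, ncols):
    nb = {z: [] for z in ids}
    for k, z in enumerate(ids):
        i, j = divmod(k, ncols)
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            k2 = (i + di) * ncols + (j + dj)
            if 0 <= j + dj < ncols and 0 <= k2 < len(ids) and 0 <= i + di:
                nb[z].append(ids[k2])
    return ZoneAdjacency(zone_ids=list(ids), neighbours=nb)


class TestFitCountGlmm:
    def test_full_fit_returns_rate_ratios_and_diagnostics(self):
        df = simulate_counts(20)
        adj = grid_adjacency(list(df["zone_id"]), 20)
        spec = ModelSpec(stratum="urban", intensity="moderate", mode="walk",
                         threshold=20.0, n_permutations=99)
        result = fit_count_glmm(df, adj, spec)
        assert result.rate_ratios is not None
        assert set(result.rate_ratios["quintile"]) == {1, 2, 3, 4, 5}
        assert result.family in ("poisson", "negbin")
        assert result.pre_moran is not None
        assert (result.rate_ratios["ci_low"] <= result.rate_ratios["rr"]).all()
        assert (result.rate_ratios["rr"] <= result.rate_ratios["ci_high"]).all()

    def test_constant_response_flagged_degenerate(self):
        df = simulate_counts(21)
        df["count"] = 0
        adj = grid_adjacency(list(df["zone_id"]), 20)
        spec = ModelSpec(stratum="rural", intensity="vigorous", mode="walk",
                         threshold=20.0, n_permutations=49)
        result = fit_count_glmm(df, adj, spec)
        assert result.rate_ratios is None
        assert "degenerate-constant" in result.flags

    def test_low_n_flagged(self):
        df = simulate_counts(22, n=20)
        df["zone_id"] = [f"z{i}" for i in range(20)]
        adj = grid_adjacency(list(df["zone_id"]), 5)
        spec = ModelSpec(stratum="small town", intensity="moderate", mode="car",
                         threshold=30.0, n_permutations=49)
        result = fit_count_glmm(df, adj, spec)
        assert "low-n" in result.flags


class TestStratifiedAnalysis:
    def build_inputs(self, n=60, seed=30):
        rng = np.random.default_rng(seed)
        zones = pd.DataFrame(
            {
                "zone_id": [f"z{i}" for i in range(n)],
                "population": rng.integers(500, 1001, n),
                "quintile": rng.integers(1, 6, n),
                "urc6": rng.integers(1, 7, n),
                "la_id": [f"LA{i % 3}" for i in range(n)],
            }
        )
        rows = []
        for mode in ("walk", "car"):
            for intensity in ("moderate", "vigorous"):
                for thr in (20.0, 30.0):
                    for z in zones["zone_id"]:
                        rows.append(
                            {"zone_id": z, "mode": mode, "intensity": intensity,
                             "threshold": thr, "count": int(rng.poisson(4)),
                             "adjusted_count": 0.0}
                        )
        counts = pd.DataFrame(rows)
        adj = grid_adjacency(list(zones["zone_id"]), 10)
        return counts, zones, adj

    def test_combinatorics_and_partition(self):
        """3 strata x 2 intensities x 2 modes x 2 thresholds attempted."""
        counts, zones, adj = self.build_inputs()
        tidy, results = stratified_analysis(
            counts, zones, adj, n_permutations=19, quad_points=5
        )
        cells = tidy.groupby(["stratum", "intensity", "mode", "threshold"]).ngroups
        assert cells == 3 * 2 * 2 * 2
        # strata partition the zones
        strat_sizes = zones["urc6"].map(urban_rural_stratum).value_counts()
        assert strat_sizes.sum() == len(zones)

    def test_empty_stratum_recorded_not_silent(self):
        counts, zones, adj = self.build_inputs()
        zones["urc6"] = 1  # everything urban: no small town or rural zones
        tidy, _ = stratified_analysis(
            counts, zones, adj, n_permutations=19, quad_points=5,
            modes=["walk"],
        )
        skipped = tidy[tidy["skipped"]]
        assert set(skipped["stratum"]) == {"small town", "rural"}
        assert (skipped["flags"] == "empty-cell").all()
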