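"""Benjamini-Hochberg, the mixed-model fitter, and the tiered contrast scheme."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import cortexmap as cm
from cortexmap.group_stats import (benjamini_hochberg,
                                   fit_random_intercept_model,
                                   tiered_area_contrasts,
                                   zscore_within_receptor)


def bh_brute_force(p, q):
    """Definition-based step-up: largest i with p_(i) <= i q / m."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


class TestBenjaminiHochberg:
    def test_hand_worked_step_up(self):
        q, rej = benjamini_hochberg([0.01, 0.02, 0.03], q=0.05)
        assert rej.all()
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_all_unit_pvalues_rejected_nothing(self):
        _, rej = benjamini_hochberg([1.0, 1.0, 1.0], q=0.05)
        assert not rej.any()

    def test_matches_definition_on_random_vectors(self, rng):
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.random(m) ** rng.uniform(0.5, 3.0)
            _, rej = benjamini_hochberg(p, q=0.05)
            assert np.array_equal(rej, bh_brute_force(p, 0.05))

    def test_adjusted_values_monotone_in_sorted_order(self, rng):
        p = rng.random(25)
        adj, _ = benjamini_hochberg(p, q=0.1)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert adj.min() >= p.min() - 1e-15
        assert np.all(adj >= p - 1e-15)

    def test_never_fewer_rejections_than_bonferroni(self, rng):
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 30)))
            _, bh = benjamini_hochberg(p, q=0.05)
            bonf = p <= 0.05 / p.size
            assert bh.sum() >= bonf.sum()
            assert np.all(bh[bonf])

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            benjamini_hochberg([0.5, 1.3])


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30),
       st.floats(0.01, 0.2))
def test_bh_property_matches_brute_force(pvals, q):
    _, rej = benjamini_hochberg(pvals, q=q)
    assert np.array_equal(rej, bh_brute_force(pvals, q))


def make_obs(n_subjects=4, n_groups=2, n_per=15, sigma_u=1.0, sigma_e=1.0,
             delta=0.0, seed=0):
    """Balanced two-factor layout: subject intercept + optional group shift."""
    rng = np.random.default_rng(seed)
    u = rng.normal(0, sigma_u, n_subjects)
    rows = []
    for s in range(n_subjects):
        for g in range(n_groups):
            for r in range(n_per):
                y = u[s] + delta * (g == 1) + rng.normal(0, sigma_e)
                rows.append((f"A{g}", f"r{r}", f"S{s}", y))
    return pd.DataFrame(rows, columns=["area", "receptor", "subject", "density"])


class TestMixedModelFitter:
    def test_zero_between_subject_variance_estimated_near_zero(self):
        obs = make_obs(n_subjects=6, sigma_u=0.0, sigma_e=1.0, seed=1)
        fit = fit_random_intercept_model(obs, random=("subject",),
                                         pvalue_method=None)
        assert fit.variance_components["subject"] < 0.05

    def test_parameter_recovery_of_group_shift(self):
        est = []
        for seed in range(60):
            obs = make_obs(delta=1.5, sigma_u=1.0, sigma_e=0.5, seed=seed)
            fit = fit_random_intercept_model(obs, random=("subject",),
                                             pvalue_method=None)
            est.append(fit.beta.iloc[1])
        assert np.mean(est) == pytest.approx(1.5, rel=0.05)

    def test_null_lrt_rejection_rate_calibrated(self):
        rejections = 0
        reps = 400
        for seed in range(reps):
            obs = make_obs(delta=0.0, seed=seed)
            fit = fit_random_intercept_model(obs, random=("subject",),
                                             reml=False, pvalue_method="lrt")
            rejections += fit.p_value < 0.05
        rate = rejections / reps
        # binomial 99% envelope around 0.05 for 400 draws
        assert 0.022 <= rate <= 0.078

    def test_matches_statsmodels_random_intercept_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        obs = make_obs(delta=0.8, sigma_u=1.2, sigma_e=0.7, seed=3)
        mine = fit_random_intercept_model(obs, random=("subject",), reml=True,
                                          pvalue_method=None)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = sm.MixedLM.from_formula("density ~ C(area)", groups="subject",
                                         data=obs).fit(reml=True)
        assert mine.beta.iloc[1] == pytest.approx(md.fe_params.iloc[1], abs=1e-4)
        assert mine.variance_components["subject"] == pytest.approx(
            float(md.cov_re.iloc[0, 0]), rel=1e-2)
        assert mine.variance_components["residual"] == pytest.approx(
            md.scale, rel=1e-2)

    def test_f_test_equals_paired_t_in_balanced_two_area_design(self):
        rng = np.random.default_rng(9)
        rows = []
        u = rng.normal(0, 1.0, 4)
        for s in range(4):
            for g, area in enumerate(("A", "B")):
                rows.append((area, "r0", f"S{s}",
                             u[s] + 0.9 * g + rng.normal(0, 0.4)))
        obs = pd.DataFrame(rows, columns=["area", "receptor", "subject", "density"])
        fit = fit_random_intercept_model(obs, random=("subject",),
                                         pvalue_method="f")
        wide = obs.pivot(index="subject", columns="area", values="density")
        t = stats.ttest_rel(wide["B"], wide["A"])
        assert fit.df_denominator == 3
        assert fit.p_value == pytest.approx(t.pvalue, rel=1e-6)

    def test_no_random_factor_reduces_to_ols(self):
        obs = make_obs(sigma_u=0.0, seed=4)
        fit = fit_random_intercept_model(obs, random=(), pvalue_method=None)
        x = (obs["area"] == "A1").to_numpy(float)
        beta1 = np.polyfit(x, obs["density"], 1)[0]
        assert fit.beta.iloc[1] == pytest.approx(beta1, abs=1e-8)

    def test_insufficient_levels_rejected(self):
        obs = make_obs()
        with pytest.raises(ValueError, match="levels"):
            fit_random_intercept_model(obs[obs.area == "A0"])


class TestTieredContrasts:
    def test_single_pair_single_receptor_q_equals_p(self):
        obs = cm.simulate_density_observations(
            seed=0, areas=["MIPd", "MIPv"], receptors=["alpha1"], base="null")
        res = tiered_area_contrasts(obs, adjacency=[("MIPd", "MIPv")], q=0.5)
        if len(res.per_receptor):
            row = res.per_receptor.iloc[0]
            assert row["q"] == pytest.approx(row["p"])
        assert res.pairwise.iloc[0]["q"] == pytest.approx(
            res.pairwise.iloc[0]["p"])

    def test_null_data_rarely_produces_tier2_survivors(self):
        survivors = 0
        for seed in range(15):
            obs = cm.simulate_density_observations(seed=700 + seed, base="null")
            res = tiered_area_contrasts(obs)
            survivors += int(res.pairwise["significant"].any())
        assert survivors <= 1

    def test_profile_wide_contrast_flagged_with_receptor_resolution(self):
        receptors = ("alpha1", "5-HT1A", "GABAB", "M1", "NMDA")
        pair_hits = rec_hits = 0
        for seed in range(10):
            obs = cm.simulate_density_observations(
                seed=seed, base="null",
                effect=("MIPd", "MIPv", receptors, 150.0))
            res = tiered_area_contrasts(obs)
            sig_pairs = res.pairwise[res.pairwise["significant"]]["pair"]
            pair_hits += "MIPd|MIPv" in sig_pairs.tolist()
            pr = res.per_receptor[res.per_receptor["significant"]]
            rec_hits += ((pr["pair"] == "MIPd|MIPv")
                         & pr["receptor"].isin(receptors)).any()
        assert pair_hits >= 9
        assert rec_hits >= 9

    def test_empty_adjacency_rejected(self):
        obs = cm.simulate_density_observations(seed=0)
        with pytest.raises(ValueError, match="adjacency"):
            tiered_area_contrasts(obs, adjacency=[])

    def test_unknown_area_in_adjacency_rejected(self):
        obs = cm.simulate_density_observations(seed=0)
        with pytest.raises(ValueError, match="unknown"):
            tiered_area_contrasts(obs, adjacency=[("MIPd", "NOPE")])

    def test_zscore_within_receptor_standardizes(self):
        obs = cm.simulate_density_observations(seed=0)
        z = zscore_within_receptor(obs)
        g = z.groupby("receptor")["z"]
        assert np.max(np.abs(g.mean())) < 1e-12
        assert np.max(np.abs(g.std(ddof=1) - 1.0)) < 1e-12
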