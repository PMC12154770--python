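"""Trajectories, selection coefficients, genomic offset, survival, census."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, logit

from grene import sim
from grene.forecast import (
    GenomicOffsetModel,
    census_trajectory,
    estimate_selection_coefficient,
    fit_logistic_trajectory,
    go_score,
    loo_predictability,
    survival_model,
)
from grene.panel import generate_founder_panel


class TestLogisticTrajectory:
    def test_constant_frequency_gives_zero_slope(self):
        res = fit_logistic_trajectory(np.full(6, 0.3), np.arange(6.0))
        assert res.beta[0] == pytest.approx(0.0, abs=1e-12)

    def test_exact_logistic_recovered(self):
        t = np.arange(8.0)
        p = expit(-1.0 + 0.3 * t)
        res = fit_logistic_trajectory(p, t)
        assert res.beta[0] == pytest.approx(0.3, abs=1e-8)
        assert res.intercept[0] == pytest.approx(-1.0, abs=1e-8)

    def test_noisy_ci_covers_generative_slope(self, rng):
        t = np.arange(6.0)
        cover = 0
        for _ in range(100):
            p = expit(-0.5 + 0.3 * t)
            obs = rng.binomial(100, p) / 100
            res = fit_logistic_trajectory(obs, t)
            tq = stats.t.ppf(0.975, len(t) - 2)
            lo = res.beta[0] - tq * res.se[0]
            hi = res.beta[0] + tq * res.se[0]
            cover += lo <= 0.3 <= hi
        assert cover >= 85

    def test_short_series_skipped(self):
        res = fit_logistic_trajectory(np.array([0.2, 0.5]), np.array([0.0, 1.0]))
        assert np.isnan(res.beta[0]) and res.n_obs[0] == 2

    def test_block_averaging(self):
        t = np.arange(5.0)
        P = np.column_stack([expit(0.2 * t), expit(0.4 * t), expit(-0.1 * t)])
        res = fit_logistic_trajectory(P, t, block_of=np.array([0, 0, 1]))
        blk = res.attrs["block"]
        assert blk.beta[0] == pytest.approx(0.3, abs=1e-8)
        assert blk.beta[1] == pytest.approx(-0.1, abs=1e-8)


class TestSelectionCoefficient:
    def test_odds_step_toy_case(self):
        # 0.5 -> 0.6 in one generation: odds go 1 -> 1.5, s = 0.5
        res = estimate_selection_coefficient(np.array([0.5, 0.6]))
        assert res.s == pytest.approx(0.5, abs=1e-9)

    def test_flat_trajectory_gives_zero(self):
        res = estimate_selection_coefficient(np.full(5, 0.4))
        assert res.s == pytest.approx(0.0, abs=1e-12)
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_sign_correct_under_simulated_selection(self):
        panel = generate_founder_panel(2, 20, 1, seed=0)
        panel.start_freq = np.array([0.5, 0.5])
        params = sim.SimParams(w_max=np.array([1.2, 1.0]), v_s_inv=0.0,
                               carrying_capacity=2000, fecundity=10)
        garden = sim.GardenDesign("g", {"bio1": 10.0}, 1, 4)
        rng = np.random.default_rng(1)
        signs = 0
        for run in range(40):
            traj = sim.simulate_experiment(panel, [garden], params,
                                           seed=int(rng.integers(2**31)),
                                           track_alleles=False)
            f = traj.acc_freq["g"][0, :, 0]
            obs = rng.binomial(100, f) / 100
            signs += estimate_selection_coefficient(obs).s > 0
        assert signs >= 38

    def test_ci_covers_generative_s(self):
        panel = generate_founder_panel(2, 20, 1, seed=0)
        panel.start_freq = np.array([0.5, 0.5])
        params = sim.SimParams(w_max=np.array([1.3, 1.0]), v_s_inv=0.0,
                               carrying_capacity=2000, fecundity=10)
        garden = sim.GardenDesign("g", {"bio1": 10.0}, 1, 4)
        rng = np.random.default_rng(7)
        cover = 0
        for run in range(100):
            traj = sim.simulate_experiment(panel, [garden], params,
                                           seed=int(rng.integers(2**31)),
                                           track_alleles=False)
            obs = rng.binomial(100, traj.acc_freq["g"][0, :, 0]) / 100
            res = estimate_selection_coefficient(obs)
            cover += res.ci_low <= 0.3 <= res.ci_high
        assert cover >= 85

    def test_single_timepoint_rejected(self):
        with pytest.raises(ValueError):
            estimate_selection_coefficient(np.array([0.4]))


class TestGenomicOffset:
    def test_noiseless_cline_reproduced_exactly(self):
        z = np.array([4.0, 8.0, 12.0, 16.0])
        a, b = -2.0, 0.25
        Y = expit(a + b * z)[:, None] * np.ones((1, 5))
        m = GenomicOffsetModel().fit(z, Y)
        assert np.allclose(m.slope_, b, atol=1e-8)
        assert np.allclose(m.predict(10.0), expit(a + b * 10), atol=1e-8)

    def test_flat_frequencies_give_flat_clines(self):
        z = np.array([5.0, 10.0, 15.0])
        Y = np.full((3, 4), 0.3)
        m = GenomicOffsetModel().fit(z, Y)
        assert np.allclose(m.predict(0.0), m.predict(20.0), atol=1e-8)

    def test_go_zero_for_matching_genotype_and_one_for_opposite(self, tiny_panel):
        z = np.array([5.0, 10.0, 15.0])
        geno = tiny_panel.imputed_genotypes()
        Y = np.tile(geno[2], (3, 1))
        m = GenomicOffsetModel(clip=1e-9).fit(z, Y)
        scores = go_score(m, 10.0, tiny_panel)
        assert scores[2] < 0.01
        anti = 1 - geno[2]
        go_anti = m.offset(10.0, anti[None, :])
        assert go_anti[0] > 0.99

    def test_go_bounded_and_invariant_to_snp_duplication(self, tiny_panel, rng):
        z = np.array([5.0, 9.0, 13.0, 17.0])
        Y = rng.random((4, tiny_panel.n_snps))
        m = GenomicOffsetModel().fit(z, Y)
        go1 = go_score(m, 11.0, tiny_panel)
        assert np.all((go1 >= 0) & (go1 <= 1))
        Ydup = np.hstack([Y, Y])
        geno_dup = np.hstack([tiny_panel.imputed_genotypes()] * 2)
        m2 = GenomicOffsetModel().fit(z, Ydup)
        go2 = m2.offset(11.0, geno_dup)
        assert np.allclose(go1, go2, atol=1e-10)

    def test_in_sample_consistency_on_adaptation_data(self):
        panel = generate_founder_panel(40, 800, 4, seed=19)
        params = sim.SimParams(w_max=1.0, v_s_inv=0.03, carrying_capacity=300,
                               fecundity=10)
        zs = np.linspace(5, 17, 8)
        gardens = [sim.GardenDesign(f"g{i}", {"bio1": float(z)}, 4, 1)
                   for i, z in enumerate(zs)]
        traj = sim.simulate_experiment(panel, gardens, params, seed=20)
        p1 = np.stack([traj.allele_freq[g][:, 1].mean(axis=0)
                       for g in traj.garden_ids])
        m = GenomicOffsetModel().fit(zs, p1)
        pred = m.predict(zs)
        rs = [stats.pearsonr(pred[i], p1[i]).statistic for i in range(len(zs))]
        assert min(rs) >= 0.9


class TestLooPredictability:
    @staticmethod
    def run_experiment(v_s_inv, seed, scorer="go"):
        panel = generate_founder_panel(50, 1000, 5, ld_decay=20, seed=seed)
        params = sim.SimParams(w_max=1.0, v_s_inv=v_s_inv, carrying_capacity=300,
                               fecundity=10)
        zs = np.linspace(5, 17, 10)
        gardens = [sim.GardenDesign(f"g{i}", {"bio1": float(z)}, 6, 1)
                   for i, z in enumerate(zs)]
        traj = sim.simulate_experiment(panel, gardens, params, seed=seed + 1)
        acc_f0 = np.stack([traj.acc_freq[g][:, 0] for g in traj.garden_ids])
        acc_f1 = np.stack([traj.acc_freq[g][:, 1] for g in traj.garden_ids])
        p1 = np.stack([traj.allele_freq[g][:, 1].mean(axis=0)
                       for g in traj.garden_ids])
        return loo_predictability(
            zs, p1, acc_f0, acc_f1, panel,
            z_origin=panel.z_origin.bio1.to_numpy(), scorer=scorer,
        )

    def test_too_few_gardens_rejected(self, tiny_panel):
        with pytest.raises(ValueError):
            loo_predictability(np.array([1.0, 2.0]), np.zeros((2, 60)),
                               np.zeros((2, 1, 10)), np.zeros((2, 1, 10)),
                               tiny_panel)

    def test_neutral_simulation_has_no_predictability(self):
        rec = self.run_experiment(0.0, 321)
        t = stats.ttest_1samp(rec.r.dropna(), 0)
        assert t.pvalue > 0.01 or abs(rec.r.mean()) < 0.05

    def test_local_adaptation_is_predictable(self):
        rec = self.run_experiment(0.03, 321)
        r = rec.r.dropna()
        t, p = stats.ttest_1samp(r, 0)
        assert r.mean() > 0.2
        assert t > 0 and p / 2 < 0.01

    def test_stabsel_augmented_scorer_not_worse(self):
        means = {}
        for scorer in ("go", "go_plus_stabsel"):
            vals = [self.run_experiment(0.03, s, scorer).r.mean()
                    for s in (321, 654)]
            means[scorer] = np.mean(vals)
        assert means["go_plus_stabsel"] >= means["go"] - 0.02

    def test_predictability_increases_with_selection_strength(self):
        means = [self.run_experiment(v, 99).r.mean() for v in (0.0, 0.01, 0.03)]
        assert means[0] < means[1] < means[2]


class TestSurvivalModel:
    @staticmethod
    def simulate_records(rng, beta, n=250):
        r2 = rng.uniform(0, 0.3, n)
        temp = rng.uniform(2, 20, n)
        eta = beta[0] + beta[1] * r2 + beta[2] * temp + beta[3] * r2 * temp
        y = (rng.random(n) < expit(eta)).astype(int)
        return pd.DataFrame({"r2": r2, "temp": temp, "survived_y3": y})

    def test_null_coefficients_covered(self, rng):
        cover = 0
        for _ in range(100):
            df = self.simulate_records(rng, [0.0, 0.0, 0.0, 0.0])
            m = survival_model(df)
            k = "r2:temp"
            cover += (m["coef"][k] - 1.96 * m["se"][k] <= 0.0
                      <= m["coef"][k] + 1.96 * m["se"][k])
        assert cover >= 85

    def test_interaction_recovered(self, rng):
        cover = 0
        for _ in range(100):
            df = self.simulate_records(rng, [-1.0, 1.0, 0.05, 2.0], n=300)
            m = survival_model(df)
            k = "r2:temp"
            cover += (m["coef"][k] - 1.96 * m["se"][k] <= 2.0
                      <= m["coef"][k] + 1.96 * m["se"][k])
        assert cover >= 85

    def test_all_survivors_degenerate_flagged(self, rng):
        df = self.simulate_records(rng, [50.0, 0.0, 0.0, 0.0])
        assert df.survived_y3.min() == 1
        m = survival_model(df)
        assert m["flagged"]

    def test_isoline_solves_fitted_model(self, rng):
        df = self.simulate_records(rng, [-2.0, 2.0, 0.1, 1.0], n=400)
        m = survival_model(df)
        if not m["flagged"]:
            t50 = m["isoline_temp_at_r2"](0.2)
            b = m["coef"]
            eta = b["const"] + b["r2"] * 0.2 + b["temp"] * t50 + b["r2:temp"] * 0.2 * t50
            assert eta == pytest.approx(0.0, abs=1e-8)


class TestCensusTrajectory:
    def test_exact_parabola_rebound(self):
        res = census_trajectory(np.array([[100.0, 20.0, 60.0]]))
        assert res["quadratic"] == pytest.approx(60.0, abs=1e-6)
        assert res["rebound"]

    def test_monotone_decline_is_linear_no_rebound(self):
        res = census_trajectory(np.array([[100.0, 60.0, 20.0]]))
        assert res["quadratic"] == pytest.approx(0.0, abs=1e-8)
        assert not res["rebound"]

    def test_constant_counts_all_zero_coefficients(self):
        res = census_trajectory(np.array([[50.0, 50.0, 50.0, 50.0]]))
        assert res["linear"] == pytest.approx(0.0, abs=1e-8)
        assert res["quadratic"] == pytest.approx(0.0, abs=1e-8)
        assert not res["rebound"]

    def test_noisy_replicates_pooled(self, rng):
        t = np.arange(5.0)
        truth = 100 - 60 * t + 12 * t**2
        counts = truth + rng.normal(0, 5, (8, 5))
        res = census_trajectory(counts, t)
        assert res["quadratic"] == pytest.approx(12.0, abs=3.0)
        assert res["rebound"]

    def test_too_few_timepoints_skipped(self):
        res = census_trajectory(np.array([[10.0, 5.0]]))
        assert not res["fitted"]
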