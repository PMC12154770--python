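"""Neutral nulls, excess-variance tests, F_ST, PCA, repeatability, H2."""

import numpy as np
import pytest
from scipy import stats

from grene import sim
from grene.drift import (
    compute_fst,
    heritability_freq_change,
    pairwise_fst,
    pca_frequency_change,
    repeatability,
    simulate_neutral_sorting,
    variance_ratio_test,
    wf_variance,
)
from grene.panel import generate_founder_panel


class TestWfVariance:
    @pytest.mark.parametrize(
        "p0,N,expected",
        [(0.5, 100, 0.00125), (0.0, 37, 0.0), (0.1, 500, 9e-05)],
    )
    def test_closed_form(self, p0, N, expected):
        assert wf_variance(p0, N) == pytest.approx(expected, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wf_variance(0.5, 0)
        with pytest.raises(ValueError):
            wf_variance(1.5, 10)


class TestNeutralSorting:
    def test_uniform_model_matches_hypergeometric_oracle(self):
        # analytic oracle: establishment multinomial + one
        # multivariate-hypergeometric reproduction step, pushed through the
        # genotype matrix
        panel = generate_founder_panel(50, 400, 2, ld_decay=5.0, seed=11)
        N, F = 50, 10
        null = simulate_neutral_sorting(
            panel.start_freq, panel, N, "uniform", 1, reps=4000, fecundity=F, seed=2
        )
        G = panel.imputed_genotypes()
        f0 = panel.start_freq
        p0 = null.p0
        ff = (N * F - N) / (N * F - 1)
        m2 = f0 @ (G**2)
        theory = (m2 - p0**2) / N * (1 + ff * (1 - 1 / N))
        ok = theory > 1e-5
        ratio = null.var[ok] / theory[ok]
        assert np.corrcoef(null.var[ok], theory[ok])[0, 1] > 0.99
        assert ratio.mean() == pytest.approx(1.0, abs=0.05)

    def test_poisson_model_is_overdispersed(self):
        panel = generate_founder_panel(20, 200, 2, seed=3)
        nu = simulate_neutral_sorting(panel.start_freq, panel, 50, "uniform",
                                      1, reps=2000, seed=5)
        npo = simulate_neutral_sorting(panel.start_freq, panel, 50, "poisson",
                                       1, reps=2000, seed=5)
        assert npo.var.mean() > nu.var.mean()

    def test_zero_generations_means_zero_variance(self, tiny_panel):
        null = simulate_neutral_sorting(tiny_panel.start_freq, tiny_panel, 50,
                                        "uniform", 0, reps=50, seed=1)
        assert np.all(null.var == 0)


class TestVarianceRatio:
    def test_self_null_gives_ratio_one(self):
        panel = generate_founder_panel(50, 500, 2, ld_decay=5.0, seed=11)
        null = simulate_neutral_sorting(panel.start_freq, panel, 50, "uniform",
                                        1, reps=2000, seed=9)
        obs = simulate_neutral_sorting(panel.start_freq, panel, 50, "uniform",
                                       1, reps=12, seed=10)
        res = variance_ratio_test(obs.delta, null, seed=0)
        assert res.ratio == pytest.approx(1.0, abs=0.25)
        assert res.ci_low <= 1.0 <= res.ci_high

    def test_scaled_observations_triple_the_ratio(self):
        panel = generate_founder_panel(50, 500, 2, ld_decay=5.0, seed=11)
        null = simulate_neutral_sorting(panel.start_freq, panel, 50, "uniform",
                                        1, reps=2000, seed=9)
        obs = simulate_neutral_sorting(panel.start_freq, panel, 50, "uniform",
                                       1, reps=12, seed=10)
        res = variance_ratio_test(np.sqrt(3) * obs.delta, null, seed=0)
        assert res.ratio == pytest.approx(3.0, rel=0.25)

    def test_selection_inflates_the_ratio(self):
        panel = generate_founder_panel(40, 500, 2, ld_decay=5.0, seed=21)
        N = 100
        null = simulate_neutral_sorting(panel.start_freq, panel, N, "uniform",
                                        1, reps=2000, seed=1)
        params = sim.SimParams(w_max=1.0, v_s_inv=0.08, carrying_capacity=N,
                               fecundity=10)
        garden = sim.GardenDesign("g", {"bio1": 16.0}, 12, 1)
        traj = sim.simulate_experiment(panel, [garden], params, seed=2)
        delta = traj.allele_freq["g"][:, 1] - panel.allele_freqs()
        res = variance_ratio_test(delta, null, seed=0)
        assert res.ratio > 1.5
        assert res.ci_low > 1.0
        assert res.mwu_p < 0.01

    def test_replicate_level_mwu_is_calibrated(self):
        # under the self-null the MWU p across repeated experiments is
        # approximately uniform; check no gross excess of small p-values
        panel = generate_founder_panel(40, 300, 2, ld_decay=5.0, seed=31)
        null = simulate_neutral_sorting(panel.start_freq, panel, 50, "uniform",
                                        1, reps=1000, seed=3)
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(60):
            obs = simulate_neutral_sorting(panel.start_freq, panel, 50,
                                           "uniform", 1, reps=12,
                                           seed=int(rng.integers(2**31)))
            ps.append(variance_ratio_test(obs.delta, null, seed=0).mwu_p)
        ps = np.asarray(ps)
        assert (ps < 0.05).mean() < 0.2
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_missing_everything_rejected(self):
        with pytest.raises(ValueError):
            variance_ratio_test(np.full((2, 200), np.nan), np.ones(200))


class TestFst:
    def test_identical_populations_have_zero_fst(self):
        p = np.linspace(0.05, 0.95, 200)
        assert compute_fst(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_fixed_differences_give_one(self):
        pa = np.tile([1.0, 0.0], 100)
        assert compute_fst(pa, 1 - pa) == pytest.approx(1.0)

    def test_hand_computed_hudson_value(self):
        # pa=0.2, pb=0.8 everywhere, no sampling correction:
        # num = 0.36, den = 0.2*0.2 + 0.8*0.8 = 0.68
        pa = np.full(150, 0.2)
        pb = np.full(150, 0.8)
        assert compute_fst(pa, pb) == pytest.approx(0.36 / 0.68)

    def test_no_shared_snps_rejected(self):
        pa = np.array([np.nan, 0.5])
        pb = np.array([0.5, np.nan])
        with pytest.raises(ValueError, match="shared"):
            compute_fst(pa, pb)

    def test_fst_grows_under_drift(self):
        # E[F_ST] vs the founders increases ~ 1 - (1 - 1/2N)^t
        panel = generate_founder_panel(40, 400, 2, seed=9)
        params = sim.SimParams(w_max=1.0, v_s_inv=0.0, carrying_capacity=100,
                               fecundity=10)
        garden = sim.GardenDesign("g", {"bio1": 10.0}, 10, 3)
        traj = sim.simulate_experiment(panel, [garden], params, seed=77)
        p0 = panel.allele_freqs()
        means = [
            np.mean([compute_fst(traj.allele_freq["g"][r, t], p0) for r in range(10)])
            for t in range(4)
        ]
        slope = np.polyfit(range(4), means, 1)[0]
        assert slope > 0
        assert means[3] > means[1]

    def test_divergent_selection_separates_between_from_within(self):
        panel = generate_founder_panel(30, 300, 2, seed=5)
        params = sim.SimParams(w_max=1.0, v_s_inv=0.05, carrying_capacity=200,
                               fecundity=10)
        gardens = [sim.GardenDesign("cold", {"bio1": 5.0}, 5, 2),
                   sim.GardenDesign("hot", {"bio1": 17.0}, 5, 2)]
        traj = sim.simulate_experiment(panel, gardens, params, seed=6)
        freq = np.vstack([traj.allele_freq["cold"][:, 2], traj.allele_freq["hot"][:, 2]])
        ids = [f"c{r}" for r in range(5)] + [f"h{r}" for r in range(5)]
        labels = {i: i[0] for i in ids}
        table = pairwise_fst(freq, ids, labels=labels)
        within = table[table.comparison == "within"].fst
        between = table[table.comparison == "between"].fst
        p = stats.mannwhitneyu(between, within, alternative="greater").pvalue
        assert p < 0.05


class TestPca:
    def test_planted_clusters_separate_on_pc1(self):
        panel = generate_founder_panel(30, 400, 2, seed=15)
        params = sim.SimParams(w_max=1.0, v_s_inv=0.05, carrying_capacity=300,
                               fecundity=10)
        gardens = [sim.GardenDesign("cold", {"bio1": 5.0}, 6, 1),
                   sim.GardenDesign("hot", {"bio1": 17.0}, 6, 1)]
        traj = sim.simulate_experiment(panel, gardens, params, seed=16)
        p0 = panel.allele_freqs()
        delta = np.vstack([traj.allele_freq["cold"][:, 1] - p0,
                           traj.allele_freq["hot"][:, 1] - p0])
        scores, _ = pca_frequency_change(delta)
        groups = np.repeat([0, 1], 6)
        r = stats.pearsonr(scores[:, 0], groups).statistic
        assert abs(r) >= 0.9

    def test_identical_samples_have_zero_pc_variance(self):
        delta = np.tile(np.linspace(-0.1, 0.1, 50), (5, 1))
        scores, var_exp = pca_frequency_change(delta)
        # rank one: all variance on PC1, later PCs empty
        assert var_exp[0] == pytest.approx(1.0)
        assert np.allclose(scores[:, 1:], 0.0, atol=1e-8)

    def test_scores_are_orthogonal_and_founder_at_origin(self, rng):
        delta = rng.normal(0, 0.05, (8, 100))
        delta[0] = 0.0  # the founder sample itself
        scores, _ = pca_frequency_change(delta)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8
        assert np.allclose(scores[0], 0.0, atol=1e-12)


class TestRepeatability:
    def test_identical_replicates_give_one(self, rng):
        d = np.tile(rng.normal(0, 1, 300), (4, 1))
        assert repeatability(d).mean_rho == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        x = np.linspace(0, 1, 100)
        res = repeatability(np.vstack([x, -x]))
        assert res.mean_rho == pytest.approx(-1.0)

    def test_selection_raises_repeatability_above_neutral(self):
        panel = generate_founder_panel(30, 200, 2, seed=41)
        garden = sim.GardenDesign("g", {"bio1": 16.0}, 12, 1)
        out = {}
        for name, v in (("neutral", 0.0), ("selected", 0.08)):
            params = sim.SimParams(w_max=1.0, v_s_inv=v, carrying_capacity=150,
                                   fecundity=10)
            traj = sim.simulate_experiment(panel, [garden], params, seed=42)
            d = traj.acc_freq["g"][:, 1] - traj.acc_freq["g"][:, 0]
            out[name] = repeatability(d, level="accession", seed=0)
        assert out["neutral"].ci_low <= 0.0 <= out["neutral"].ci_high + 0.05
        assert out["selected"].mean_rho > 0.3
        assert out["selected"].ci_low > 0.0

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            repeatability(np.ones((1, 50)))


class TestHeritability:
    def test_pure_accession_signal_gives_one(self, rng):
        effect = rng.normal(0, 1, 50)
        d = np.tile(effect, (6, 1))
        assert heritability_freq_change(d).h2 == pytest.approx(1.0)

    def test_pure_noise_gives_near_zero(self, rng):
        h2s = [heritability_freq_change(rng.normal(0, 1, (6, 50))).h2
               for _ in range(200)]
        assert np.mean(h2s) < 0.1

    def test_equal_variance_components_give_half(self, rng):
        # oracle: sigma2_acc = sigma2_res = 1 -> H2 = 0.5
        h2s = []
        for _ in range(300):
            effect = rng.normal(0, 1, 60)
            d = effect + rng.normal(0, 1, (8, 60))
            h2s.append(heritability_freq_change(d).h2)
        assert np.mean(h2s) == pytest.approx(0.5, abs=0.03)

    def test_degenerate_input_flagged(self):
        res = heritability_freq_change(np.zeros((3, 20)))
        assert not res.defined
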