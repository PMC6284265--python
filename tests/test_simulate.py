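import numpy as np
import pytest
from scipy.special import expit

from longsamgsr.simulate import (SCENARIO1_TERMS, SCENARIO2_TERMS,
                                 SimulationDesign, build_mean_shift_dataset,
                                 build_scenario1, build_scenario2,
                                 generate_base_expression, run_replicates,
                                 simulate_outcome)


def lag1_autocorr(expr):
    """Pooled empirical lag-1 autocorrelation of standardized trajectories."""
    z = (expr - expr.mean(axis=(1, 2), keepdims=True)) / expr.std(axis=(1, 2), keepdims=True)
    a = z[:, :, :-1].ravel()
    b = z[:, :, 1:].ravel()
    return np.corrcoef(a, b)[0, 1]


class TestBaseExpression:
    @pytest.mark.parametrize("rho", [0.0, 0.8])
    def test_empirical_autocorrelation(self, rho):
        base = generate_base_expression(G=1000, n=100, T=5, rho=rho, seed=1)
        assert lag1_autocorr(base.expr) == pytest.approx(rho, abs=0.05)

    def test_same_seed_identical(self):
        a = generate_base_expression(50, 10, 3, seed=9)
        b = generate_base_expression(50, 10, 3, seed=9)
        assert np.array_equal(a.expr, b.expr)

    def test_block_correlation_raises_between_gene_correlation(self):
        plain = generate_base_expression(40, 60, 4, rho=0.3, seed=2)
        blocked = generate_base_expression(40, 60, 4, rho=0.3, seed=2,
                                           block_size=10, block_rho=0.8)

        def mean_abs_corr(expr):
            flat = expr.reshape(expr.shape[0], -1)
            c = np.corrcoef(flat)
            return np.abs(c[np.triu_indices_from(c, 1)]).mean()

        assert mean_abs_corr(blocked.expr) > mean_abs_corr(plain.expr) + 0.1


class TestSimulateOutcome:
    def test_all_zero_covariates_give_half_probability(self):
        base = generate_base_expression(3, 2000, 2, seed=0)
        base.expr[0] = 0.0
        design = SimulationDesign(causal_terms=[("gene_0", 1, 1.0)],
                                  n_noise=2, n_subjects=2000, T=2,
                                  standardize=False)
        y = simulate_outcome(base, design, seed=1)
        assert y.mean() == pytest.approx(0.5, abs=0.03)

    def test_huge_beta_tracks_covariate_sign(self):
        base = generate_base_expression(2, 500, 1, seed=3)
        design = SimulationDesign(causal_terms=[("gene_0", 1, 50.0)],
                                  n_noise=1, n_subjects=500, T=1)
        y = simulate_outcome(base, design, seed=3)
        x = base.expr[0, :, 0]
        sign = (x > x.mean()).astype(int)
        assert (y == sign).mean() > 0.95

    def test_scenario1_coefficients_give_balanced_prevalence(self):
        base = generate_base_expression(4, 10_000, 5, rho=0.5, seed=4)
        ids = ["causal_joint", "causal_single", "n1", "n2"]
        base.gene_ids = ids
        design = SimulationDesign(causal_terms=list(SCENARIO1_TERMS),
                                  n_noise=2, n_subjects=10_000, T=5)
        y = simulate_outcome(base, design, seed=4)
        assert y.mean() == pytest.approx(0.5, abs=0.03)

    def test_label_mean_matches_bernoulli_parameter_mean(self):
        base = generate_base_expression(2, 10_000, 2, seed=6)
        design = SimulationDesign(causal_terms=[("gene_0", 1, 0.7)],
                                  n_noise=1, n_subjects=10_000, T=2)
        x = base.expr[0, :, 0]
        p = expit(0.7 * (x - x.mean()) / x.std())
        y = simulate_outcome(base, design, seed=6)
        assert y.mean() == pytest.approx(p.mean(), abs=0.02)

    def test_zero_coefficient_rejected(self):
        with pytest.raises(ValueError):
            SimulationDesign(causal_terms=[("g", 1, 0.0)], n_noise=1,
                             n_subjects=10, T=2)


class TestScenarios:
    def test_scenario1_shape_and_terms(self):
        ds, design = build_scenario1(seed=5, n_noise=98, n_subjects=20)
        assert ds.n_genes == 100
        assert ds.n_times == 5
        assert len(design.causal_terms) == 5
        assert design.causal_genes == ["causal_joint", "causal_single"]
        assert ds.labels is not None and ds.mask.all()

    def test_scenario2_opposite_signs(self):
        _, design = build_scenario2(seed=5, n_noise=48, n_subjects=20)
        betas = [b for _, _, b in design.causal_terms]
        assert len(betas) == 2 and np.sign(betas[0]) != np.sign(betas[1])
        assert [t for _, t, _ in design.causal_terms] == [1, 5]

    def test_causal_genes_not_in_noise_pool(self):
        ds, design = build_scenario1(seed=1, n_noise=50, n_subjects=20)
        noise_ids = [g for g in ds.gene_ids if g not in design.causal_genes]
        assert len(noise_ids) == 50
        assert set(design.causal_genes).isdisjoint(noise_ids)

    def test_noise_pool_differs_between_seeds(self):
        a, _ = build_scenario1(seed=1, n_noise=30, n_subjects=20)
        b, _ = build_scenario1(seed=2, n_noise=30, n_subjects=20)
        assert not np.array_equal(a.expr, b.expr)

    def test_mean_shift_dataset_effect_size(self):
        ds, (g, t) = build_mean_shift_dataset(G=50, n_cases=20, n_controls=20,
                                              T=3, causal_time=2, shift_sd=2.0,
                                              seed=7)
        cases = ds.expr[g, ds.labels == 1, t - 1]
        ctrls = ds.expr[g, ds.labels == 0, t - 1]
        pooled = ds.expr[g, :, t - 1].std()
        assert (cases.mean() - ctrls.mean()) / pooled > 1.0


class TestRunReplicates:
    def test_single_replicate_frequencies_are_zero_or_hundred(self):
        summary = run_replicates(
            build_scenario1, R=1, seed=3, B=50, c_cutoff=0.05,
            builder_kwargs={"n_noise": 48, "n_subjects": 24, "beta_scale": 5.0})
        vals = summary.freq.to_numpy()
        assert np.isin(vals, (0.0, 100.0)).all()
        assert summary.n_effective == 1

    def test_summary_layout(self):
        summary = run_replicates(
            build_scenario2, R=2, seed=4, B=50, c_cutoff=0.05,
            builder_kwargs={"n_noise": 28, "n_subjects": 24})
        assert list(summary.freq.index) == ["causal_up", "causal_down"]
        assert summary.freq.shape == (2, 5)
        frame = summary.to_frame()
        assert "# genes" in frame.index
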