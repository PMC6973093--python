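"""Variable-rates MCMC: likelihood identities, prior sampling, posterior summaries."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ratescape.gls import RegressionSpec, build_design, gls_fit
from ratescape.simulate import (
    ShiftSpec,
    SimulationConfig,
    find_clade,
    simulate_dataset,
    simulate_tree,
)
from ratescape.vr import (
    ChainSettings,
    VariableRatesPriors,
    VariableRatesRegression,
    VariableRatesSampler,
    VRPosteriorSample,
    compute_px,
    compute_px_diff,
    effective_sample_size,
    mcmc_step,
    run_chain,
    vr_loglik,
)


def _sampler(ds, spec, **kwargs):
    df = ds.table.reindex_to(ds.tree.tip_labels)
    X, y = build_design(spec, df)
    return VariableRatesSampler(X.to_numpy(float), y, ds.tree, **kwargs)


class TestVrLoglik:
    def test_all_scalars_one_equals_gls(self, small_dataset, spec):
        fit = gls_fit(spec, small_dataset.table, small_dataset.tree)
        sample = VRPosteriorSample(
            beta=fit.coef.to_numpy(),
            sigma2=fit.sigma2,
            r=np.ones(small_dataset.tree.n_branches),
            loglik=np.nan,
        )
        ll = vr_loglik(sample, spec, small_dataset.table, small_dataset.tree)
        assert ll == pytest.approx(fit.loglik, abs=1e-9)

    def test_scale_confound_invariance(self, small_dataset, spec):
        """(r -> c r, sigma_b^2 -> sigma_b^2/c) leaves the likelihood fixed."""
        rng = np.random.default_rng(2)
        B = small_dataset.tree.n_branches
        r = np.exp(rng.normal(0, 0.5, B))
        base = VRPosteriorSample(beta=np.array([-2.0, 0.7]), sigma2=0.06, r=r, loglik=np.nan)
        ll0 = vr_loglik(base, spec, small_dataset.table, small_dataset.tree)
        for c in (0.2, 5.0, 123.0):
            scaled = VRPosteriorSample(
                beta=base.beta, sigma2=0.06 / c, r=r * c, loglik=np.nan
            )
            ll = vr_loglik(scaled, spec, small_dataset.table, small_dataset.tree)
            assert ll == pytest.approx(ll0, abs=1e-9)

    def test_matches_dense_mvn_oracle(self, spec):
        from scipy.stats import multivariate_normal

        from ratescape.gls import phylo_covariance

        ds = simulate_dataset(SimulationConfig(n_tips=10, seed=21))
        rng = np.random.default_rng(3)
        r = np.exp(rng.normal(0, 0.6, ds.tree.n_branches))
        s = VRPosteriorSample(beta=np.array([-1.9, 0.6]), sigma2=0.04, r=r, loglik=np.nan)
        ll = vr_loglik(s, spec, ds.table, ds.tree)
        df = ds.table.reindex_to(ds.tree.tip_labels)
        X = np.column_stack([np.ones(10), df["log_body"]])
        resid = df["log_testes"].to_numpy() - X @ s.beta
        V = 0.04 * phylo_covariance(ds.tree.scaled_by(r))
        assert ll == pytest.approx(
            multivariate_normal(mean=np.zeros(10), cov=V).logpdf(resid), abs=1e-8
        )

    def test_negative_scalars_rejected(self, small_dataset, spec):
        s = VRPosteriorSample(
            beta=np.array([-2.0, 0.7]),
            sigma2=0.05,
            r=-np.ones(small_dataset.tree.n_branches),
            loglik=np.nan,
        )
        with pytest.raises(ValueError):
            vr_loglik(s, spec, small_dataset.table, small_dataset.tree)


class TestSampler:
    def test_fixed_seed_identical_trajectory(self, small_dataset, spec):
        settings = ChainSettings(iterations=2000, burn_in=500, thin=5, seed=4)
        t1 = run_chain(spec, small_dataset.table, small_dataset.tree, settings, ess_warn=0)
        t2 = run_chain(spec, small_dataset.table, small_dataset.tree, settings, ess_warn=0)
        assert np.array_equal(t1.r, t2.r)
        assert np.array_equal(t1.beta, t2.beta)

    def test_trace_length_bookkeeping(self, small_dataset, spec):
        settings = ChainSettings(iterations=100_00, burn_in=2_000, thin=10, seed=0)
        trace = run_chain(spec, small_dataset.table, small_dataset.tree, settings, ess_warn=0)
        assert len(trace) == (10_000 - 2_000) // 10

    def test_mcmc_step_advances_in_place(self, small_dataset, spec):
        s = _sampler(small_dataset, spec)
        rng = np.random.default_rng(0)
        st_ = s.init_state(rng)
        out = mcmc_step(s, st_, rng)
        assert out is st_

    def test_prior_sampling_recovers_activation(self, spec):
        """Likelihood off: innovation fraction matches p_active within 3 MC SEs."""
        ds = simulate_dataset(SimulationConfig(n_tips=10, seed=30))
        s = _sampler(ds, spec, likelihood_off=True)
        rng = np.random.default_rng(5)
        st_ = s.init_state(rng)
        fracs = []
        for it in range(150_000):
            s.step(st_, rng)
            if it % 10 == 0:
                fracs.append(st_.innov.mean())
        fracs = np.asarray(fracs)
        # batch means standard error (chain is autocorrelated)
        nb = 30
        batches = fracs[: len(fracs) // nb * nb].reshape(nb, -1).mean(axis=1)
        se = batches.std(ddof=1) / math.sqrt(nb)
        assert abs(fracs.mean() - 0.05) < 3 * se + 1e-4

    def test_posterior_beta_agrees_with_gls_on_fixed_tree_data(self, spec):
        """No planted heterogeneity: posterior means sit near the ML estimates."""
        ok = 0
        total = 0
        for seed in range(4):
            ds = simulate_dataset(SimulationConfig(n_tips=40, seed=seed + 50))
            fit = gls_fit(spec, ds.table, ds.tree)
            trace = run_chain(
                spec,
                ds.table,
                ds.tree,
                ChainSettings(iterations=20_000, burn_in=5_000, thin=10, seed=seed),
                ess_warn=0,
            )
            for j in range(2):
                sd = trace.beta[:, j].std()
                total += 1
                if abs(trace.beta[:, j].mean() - fit.coef.iloc[j]) < 2 * sd:
                    ok += 1
        assert ok >= total - 1

    def test_shift_recovery_elevates_clade_medians(self, spec):
        """Planted x8 clade: within-clade median r above the outside median."""
        tree = simulate_tree(SimulationConfig(n_tips=50, seed=33))
        a, b = find_clade(tree, 10, 12, min_stem=0.05)
        ds = simulate_dataset(
            SimulationConfig(n_tips=50, seed=33, shifts=(ShiftSpec(anchor=(a, b), multiplier=8.0),))
        )
        trace = run_chain(
            spec,
            ds.table,
            ds.tree,
            ChainSettings(iterations=40_000, burn_in=10_000, thin=10, seed=1),
            ess_warn=0,
        )
        node = tree.mrca((a, b))
        clade = tree.clade_nodes(node) - 1
        med = np.median(trace.r, axis=0)
        outside = np.setdiff1d(np.arange(tree.n_branches), clade)
        assert np.median(med[clade]) > np.median(med[outside])

    def test_estimator_front_end(self, small_dataset, spec):
        from sklearn.base import clone

        df = small_dataset.table.reindex_to(small_dataset.tree.tip_labels)
        X, y = build_design(spec, df)
        est = VariableRatesRegression(
            tree=small_dataset.tree, iterations=3000, burn_in=1000, thin=10, seed=0
        )
        clone(est)  # sklearn parameter contract
        est.fit(X, y)
        assert est.trace_.r.shape[1] == small_dataset.tree.n_branches
        assert est.predict(X).shape == y.shape


class TestPx:
    def test_counting_example(self):
        assert compute_px([-0.1, 0.2, 0.3, 0.4]) == pytest.approx(0.25)

    def test_one_sided(self):
        assert compute_px([0.5, 1.0, 2.0]) == 0.0

    def test_symmetric(self):
        assert compute_px([-2.0, -1.0, 1.0, 2.0]) == pytest.approx(0.5)

    def test_all_zero_degenerate_convention(self):
        px, different = compute_px_diff(np.ones(10), np.ones(10))
        assert px == 0.5 and not different

    def test_always_positive_difference(self):
        px, different = compute_px_diff(np.arange(1, 5.0), np.zeros(4))
        assert px == 0.0 and different

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_px_diff([1.0], [1.0, 2.0])

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=200))
    def test_px_bounds(self, xs):
        assert 0.0 <= compute_px(xs) <= 0.5


class TestEss:
    def test_iid_near_n(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=4000)
        assert effective_sample_size(x) > 2500

    def test_ar1_matches_theory(self):
        """AR(1) with coefficient phi has ESS ~ n (1-phi)/(1+phi)."""
        rng = np.random.default_rng(1)
        phi = 0.9
        n = 40_000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        expected = n * (1 - phi) / (1 + phi)
        assert effective_sample_size(x) == pytest.approx(expected, rel=0.25)

    def test_constant_series(self):
        assert effective_sample_size(np.ones(100)) == 100.0
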