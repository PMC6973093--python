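"""The synthetic-data generator: determinism, planted structure, noise model."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

from ratescape.gls import phylo_covariance
from ratescape.simulate import (
    ShiftSpec,
    SimulationConfig,
    TrendSpec,
    find_clade,
    find_disjoint_clades,
    plant_directional_trend,
    simulate_dataset,
    simulate_tree,
    true_branch_scalars,
)
from ratescape.traits import TraitTable
from ratescape.tree import parse_newick


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_tips": 2},
            {"birth_rate": -1.0},
            {"mating_frequencies": {"birds": {"monogamy": 0.5, "polygyny": 0.2}}},
            {"intercepts": {"birds": -2.0, "fish": -1.0}},  # slopes don't cover fish
            {"body_mode": "uniform"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_shift_multiplier_positive(self):
        with pytest.raises(ValueError):
            ShiftSpec(anchor=("a", "b"), multiplier=0.0)


class TestSimulateTree:
    def test_two_tip_cherry_ultrametric(self):
        t = simulate_tree(SimulationConfig(n_tips=3, seed=0))
        d = list(t.tip_depths().values())
        assert max(d) - min(d) < 1e-9

    def test_seeded_determinism(self):
        cfg = SimulationConfig(n_tips=40, seed=9)
        assert simulate_tree(cfg).to_newick() == simulate_tree(cfg).to_newick()

    def test_pure_birth_counts(self):
        t = simulate_tree(SimulationConfig(n_tips=100, seed=1, death_rate=0.0))
        assert t.n_tips == 100
        assert t.n_nodes - t.n_tips == 99  # binary

    def test_height_normalized(self):
        t = simulate_tree(SimulationConfig(n_tips=30, seed=2))
        assert max(t.tip_depths().values()) == pytest.approx(1.0)


class TestSimulateTraits:
    def test_zero_noise_exactly_linear(self):
        ds = simulate_dataset(SimulationConfig(n_tips=20, seed=4, sigma2_b=0.0))
        df = ds.table.data
        resid = df["log_testes"] - (-2.0 + 0.67 * df["log_body"])
        assert np.allclose(resid, 0.0, atol=1e-12)

    def test_byte_identical_outputs(self):
        cfg = SimulationConfig(n_tips=25, seed=11)
        a = simulate_dataset(cfg).table.data.to_csv(index=False)
        b = simulate_dataset(cfg).table.data.to_csv(index=False)
        assert a == b

    def test_planted_variance_shift_matches_analytic_covariance(self):
        """Empirical residual variance ratio approaches the analytic one."""
        tree = simulate_tree(SimulationConfig(n_tips=40, seed=5))
        a, b = find_clade(tree, 10, 14)
        cfg = SimulationConfig(
            n_tips=40, seed=5, shifts=(ShiftSpec(anchor=(a, b), multiplier=8.0),)
        )
        node = tree.mrca((a, b))
        idx = tree.clade_tip_indices(node)
        out = np.setdiff1d(np.arange(tree.n_tips), idx)
        Vs = phylo_covariance(tree.scaled_by(true_branch_scalars(tree, cfg)))
        expect_in = 0.05 * np.mean(np.diag(Vs)[idx])
        expect_out = 0.05 * np.mean(np.diag(Vs)[out])
        # Monte-Carlo oracle: residual draws under the generator
        reps = 3000
        rng = np.random.default_rng(0)
        L = linalg.cholesky(0.05 * Vs, lower=True)
        draws = L @ rng.standard_normal((tree.n_tips, reps))
        emp_in = float(np.mean(draws[idx] ** 2))
        emp_out = float(np.mean(draws[out] ** 2))
        assert emp_in / emp_out == pytest.approx(expect_in / expect_out, rel=0.1)
        assert expect_in / expect_out > 3.0  # the x8 shift is visible

    def test_sister_tip_residual_correlation(self):
        """Two sister tips sharing 90% of their path correlate at ~0.9."""
        t = parse_newick("((A:0.1,B:0.1):0.9,C:1.0):0;")
        V = phylo_covariance(t)
        rho_expected = V[0, 1] / V[0, 0]
        assert rho_expected == pytest.approx(0.9)
        rng = np.random.default_rng(1)
        L = linalg.cholesky(V, lower=True)
        draws = L @ rng.standard_normal((3, 10_000))
        rho = np.corrcoef(draws[0], draws[1])[0, 1]
        assert rho == pytest.approx(0.9, abs=0.02)

    def test_mean_shift_offsets_tips(self):
        tree = simulate_tree(SimulationConfig(n_tips=20, seed=6))
        a, b = find_clade(tree, 4, 8)
        base = simulate_dataset(SimulationConfig(n_tips=20, seed=6, sigma2_b=0.0))
        shifted = simulate_dataset(
            SimulationConfig(
                n_tips=20,
                seed=6,
                sigma2_b=0.0,
                shifts=(ShiftSpec(anchor=(a, b), kind="mean", mean_offset=-0.6),),
            )
        )
        idx = tree.clade_tip_indices(tree.mrca((a, b)))
        delta = shifted.table.data["log_testes"] - base.table.data["log_testes"]
        assert np.allclose(delta.iloc[idx], -0.6)
        assert np.allclose(np.delete(delta.to_numpy(), idx), 0.0)

    def test_whitened_residuals_standard_normal(self):
        """Under the null generator, GLS-whitened residuals are iid N(0,1)."""
        passed = 0
        for seed in range(100):
            ds = simulate_dataset(SimulationConfig(n_tips=30, seed=seed + 300))
            df = ds.table.data
            resid = df["log_testes"] - (-2.0 + 0.67 * df["log_body"])
            V = 0.05 * phylo_covariance(ds.tree)
            z = linalg.solve_triangular(
                linalg.cholesky(V, lower=True), resid.to_numpy(), lower=True
            )
            if stats.kstest(z, "norm").pvalue > 0.01:
                passed += 1
        assert passed >= 95


class TestPlantedTrend:
    def _setup(self, coeff):
        tree = simulate_tree(SimulationConfig(n_tips=30, seed=8))
        a, b = find_clade(tree, 8, 12)
        return SimulationConfig(
            n_tips=30,
            seed=8,
            shifts=(ShiftSpec(anchor=(a, b), multiplier=8.0),),
            trend=TrendSpec(category="monogamy", coefficient=coeff) if coeff is not None else None,
        )

    def test_zero_coefficient_identity(self):
        base = simulate_dataset(self._setup(None))
        planted = plant_directional_trend(base.table, base.tree, self._setup(0.0))
        pd.testing.assert_frame_equal(base.table.data, planted.data)

    def test_offsets_match_direct_arithmetic(self):
        """Planted offsets reproduce coefficient x centred path-wise rate."""
        t = parse_newick("(((a:1,b:1):1,c:2):1,(d:1.5,e:1.5):1.5):0;")
        df = pd.DataFrame(
            {
                "species": ["a", "b", "c", "d", "e"],
                "log_testes": np.zeros(5),
                "log_body": np.ones(5),
                "clade_class": "birds",
                "mating_system": ["monogamy"] * 3 + ["polygyny"] * 2,
            }
        )
        table = TraitTable(df)
        cfg = SimulationConfig(
            n_tips=5,
            seed=0,
            shifts=(ShiftSpec(anchor=("a", "b"), multiplier=4.0),),
            trend=TrendSpec(category="monogamy", coefficient=-0.5),
            tree_height=None,
        )
        out = plant_directional_trend(table, t, cfg)
        # path-wise rates by hand: the x4 clade is {a,b} with stem+2 branches
        # a: 1 + 4*(1+1) = 9; b: 9; c: 1+2 = 3; d: 3; e: 3; mean 5.4
        expect = -0.5 * (np.array([9.0, 9.0, 3.0]) - 5.4)
        got = out.data.set_index("species")["log_testes"]
        assert np.allclose(got.loc[["a", "b", "c"]], expect)
        assert np.allclose(got.loc[["d", "e"]], 0.0)

    def test_single_tip_category_gets_its_offset(self):
        t = parse_newick("(((a:1,b:1):1,c:2):1,(d:1.5,e:1.5):1.5):0;")
        df = pd.DataFrame(
            {
                "species": list("abcde"),
                "log_testes": np.zeros(5),
                "log_body": np.ones(5),
                "clade_class": "birds",
                "mating_system": ["polyandry"] + ["monogamy"] * 4,
            }
        )
        cfg = SimulationConfig(
            n_tips=5,
            seed=0,
            shifts=(ShiftSpec(anchor=("a", "b"), multiplier=4.0),),
            trend=TrendSpec(category="polyandry", coefficient=1.0),
            tree_height=None,
        )
        out = plant_directional_trend(TraitTable(df), t, cfg)
        got = out.data.set_index("species")["log_testes"]
        assert got.loc["a"] == pytest.approx(9.0 - 5.4)  # only tip in its category
        assert np.allclose(got.loc[["b", "c", "d", "e"]], 0.0)

    def test_absent_category_rejected(self):
        base = simulate_dataset(self._setup(None))
        cfg = self._setup(-0.5)
        cfg = SimulationConfig(
            n_tips=30,
            seed=8,
            shifts=cfg.shifts,
            trend=TrendSpec(category="polyandry", coefficient=-0.5),
            mating_frequencies={"birds": {"monogamy": 1.0}},
        )
        table = base.table
        table.data["mating_system"] = "monogamy"
        with pytest.raises(ValueError, match="absent"):
            plant_directional_trend(table, base.tree, cfg)


class TestCladeFinders:
    def test_disjoint_clades(self):
        tree = simulate_tree(SimulationConfig(n_tips=60, seed=13))
        anchors = find_disjoint_clades(tree, [(10, 16), (6, 10), (4, 6)])
        sets = [set(tree.clade_tip_indices(tree.mrca(a)).tolist()) for a in anchors]
        assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) and not (sets[1] & sets[2])
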