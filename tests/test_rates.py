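"""Posterior post-processing: classification, shifts, scaled trees, path-wise rates."""

import numpy as np
import pandas as pd
import pytest

from ratescape.gls import RegressionSpec
from ratescape.rates import (
    detect_heritable_shifts,
    flag_mean_shift,
    median_scaled_tree,
    pathwise_rates,
    summarize_branch_rates,
)
from ratescape.simulate import ShiftSpec, SimulationConfig, find_clade, simulate_dataset, simulate_tree
from ratescape.traits import TraitTable
from ratescape.tree import parse_newick


def ladder_clade(labels):
    out = f"({labels[0]}:1,{labels[1]}:1):1"
    for lab in labels[2:]:
        out = f"({out},{lab}:1):1"
    return out


def clade_tree(n_clade):
    """Tree whose first child of the root is an n_clade-tip ladder clade."""
    clade = ladder_clade([f"c{i}" for i in range(n_clade)])
    out = ladder_clade([f"o{i}" for i in range(4)])
    return parse_newick(f"({clade},{out}):0;")


class TestSummaries:
    def test_fraction_counting(self, trace_factory, three_tip_tree):
        B = three_tip_tree.n_branches
        r = np.ones((4, B))
        r[:, 0] = [2.0, 1.5, 0.9, 3.0]
        summ = summarize_branch_rates(trace_factory(three_tip_tree, r), three_tip_tree)
        assert summ[0].frac_gt1 == pytest.approx(0.75)
        assert summ[0].classification == "increase"

    def test_all_inactive_background(self, trace_factory, three_tip_tree):
        r = np.ones((4, three_tip_tree.n_branches))
        summ = summarize_branch_rates(trace_factory(three_tip_tree, r), three_tip_tree)
        assert all(s.classification == "background" for s in summ)

    def test_exact_half_is_background(self, trace_factory, three_tip_tree):
        """Strict rule: a tie at exactly 50% is not classified."""
        r = np.ones((4, three_tip_tree.n_branches))
        r[:, 0] = [2.0, 2.0, 0.5, 0.5]
        summ = summarize_branch_rates(trace_factory(three_tip_tree, r), three_tip_tree)
        assert summ[0].frac_gt1 == 0.5
        assert summ[0].classification == "background"

    def test_empty_trace_rejected(self, trace_factory, three_tip_tree):
        tr = trace_factory(three_tip_tree, np.ones((0, three_tip_tree.n_branches)))
        with pytest.raises(ValueError):
            summarize_branch_rates(tr, three_tip_tree)

    def test_classification_invariant_to_iteration_order(self, trace_factory):
        t = clade_tree(6)
        rng = np.random.default_rng(0)
        r = np.exp(rng.normal(0, 0.5, size=(50, t.n_branches)))
        tr = trace_factory(t, r)
        base = [s.classification for s in summarize_branch_rates(tr, t)]
        perm = rng.permutation(50)
        tr2 = trace_factory(t, r[perm])
        assert [s.classification for s in summarize_branch_rates(tr2, t)] == base


class TestHeritableShifts:
    def _clade_trace(self, factory, tree, n_clade, draws=(2.0, 3.0, 2.5, 4.0)):
        stem = tree.mrca([f"c{i}" for i in range(n_clade)])
        clade_branches = tree.clade_nodes(stem) - 1
        r = np.ones((len(draws), tree.n_branches))
        for k, v in enumerate(draws):
            r[k, clade_branches] = v
        return factory(tree, r), stem

    def test_twelve_tip_heritable(self, trace_factory):
        """Clade-wide elevation with exact ties: one heritable increase of 12."""
        t = clade_tree(12)
        tr, stem = self._clade_trace(trace_factory, t, 12)
        reports = detect_heritable_shifts(summarize_branch_rates(tr, t), tr, t)
        assert len(reports) == 1
        rep = reports[0]
        assert rep.kind == "heritable" and rep.size == 12
        assert rep.direction == "increase"
        assert rep.anchor_node == stem
        assert rep.max_descendant_diff_frac == 0.0  # exact inheritance ties

    def test_nine_tip_is_incipient(self, trace_factory):
        t = clade_tree(9)
        tr, _ = self._clade_trace(trace_factory, t, 9)
        reports = detect_heritable_shifts(summarize_branch_rates(tr, t), tr, t)
        assert [r.kind for r in reports] == ["incipient"]

    def test_all_inactive_empty_report(self, trace_factory):
        t = clade_tree(12)
        tr = trace_factory(t, np.ones((4, t.n_branches)))
        assert detect_heritable_shifts(summarize_branch_rates(tr, t), tr, t) == []

    def test_nested_subclade_not_double_reported(self, trace_factory):
        """A subclade sharing the inherited rate is never reported separately."""
        t = clade_tree(12)
        tr, stem = self._clade_trace(trace_factory, t, 12)
        reports = detect_heritable_shifts(summarize_branch_rates(tr, t), tr, t)
        assert len(reports) == 1 and reports[0].anchor_node == stem

    def test_decrease_direction(self, trace_factory):
        t = clade_tree(12)
        tr, stem = self._clade_trace(trace_factory, t, 12, draws=(0.2, 0.5, 0.4, 0.3))
        reports = detect_heritable_shifts(summarize_branch_rates(tr, t), tr, t)
        assert reports[0].direction == "decrease"

    def test_single_species_shift(self, trace_factory):
        t = clade_tree(12)
        tip_node = t._node_of_label["o0"]
        r = np.ones((4, t.n_branches))
        r[:, tip_node - 1] = [3.0, 4.0, 5.0, 2.0]
        tr = trace_factory(t, r)
        reports = detect_heritable_shifts(summarize_branch_rates(tr, t), tr, t)
        assert [x.kind for x in reports] == ["single-species"]
        assert reports[0].size == 1

    def test_stem_only_candidate_needs_flag(self, trace_factory):
        """Uninherited stem elevation appears only with include_single_branch."""
        t = clade_tree(12)
        stem = t.mrca([f"c{i}" for i in range(12)])
        r = np.ones((4, t.n_branches))
        r[:, stem - 1] = [5.0, 6.0, 7.0, 8.0]
        tr = trace_factory(t, r)
        summ = summarize_branch_rates(tr, t)
        assert detect_heritable_shifts(summ, tr, t) == []
        reports = detect_heritable_shifts(summ, tr, t, include_single_branch=True)
        assert [x.kind for x in reports] == ["single-branch"]


class TestMeanShiftFlag:
    def _dataset_and_trace(self, trace_factory, kind, offset=0.0, mult=1.0):
        tree = simulate_tree(SimulationConfig(n_tips=30, seed=44))
        a, b = find_clade(tree, 6, 10, min_stem=0.05)
        node = tree.mrca((a, b))
        shift = (
            ShiftSpec(anchor=(a, b), kind="mean", mean_offset=offset)
            if kind == "mean"
            else ShiftSpec(anchor=(a, b), multiplier=mult)
        )
        ds = simulate_dataset(SimulationConfig(n_tips=30, seed=44, shifts=(shift,)))
        r = np.ones((4, tree.n_branches))
        if kind == "mean":  # posterior isolates the elevation on the stem
            r[:, node - 1] = [5.0, 6.0, 7.0, 8.0]
        else:  # variance shift: whole clade inherits the elevation
            r[:, tree.clade_nodes(node) - 1] = np.array([[5.0, 6.0, 7.0, 8.0]]).T
        return ds, trace_factory(ds.tree, r), node

    def test_planted_intercept_offset_flagged(self, trace_factory):
        ds, tr, node = self._dataset_and_trace(trace_factory, "mean", offset=-0.6)
        reports = detect_heritable_shifts(
            summarize_branch_rates(tr, ds.tree), tr, ds.tree, include_single_branch=True
        )
        assert reports and reports[0].anchor_node == node
        flagged = flag_mean_shift(reports[0], ds.table, ds.tree, tr)
        assert flagged.kind == "mean-shift-candidate"
        assert flagged.mean_shift_offset < 0
        assert flagged.mean_shift_p < 0.05

    def test_pure_variance_shift_not_flagged(self, trace_factory):
        """An inherited rate increase is not relabelled as a mean shift."""
        ds, tr, node = self._dataset_and_trace(trace_factory, "variance", mult=8.0)
        reports = detect_heritable_shifts(
            summarize_branch_rates(tr, ds.tree), tr, ds.tree, include_single_branch=True
        )
        assert reports
        flagged = flag_mean_shift(reports[0], ds.table, ds.tree, tr)
        assert flagged.kind != "mean-shift-candidate"

    def test_collinear_dummy_skipped(self, trace_factory):
        ds, tr, node = self._dataset_and_trace(trace_factory, "mean", offset=-0.6)
        # make the clade coincide exactly with a taxonomic class so the
        # clade dummy is collinear with the class term
        df = ds.table.data.copy()
        clade_species = [ds.tree.tip_labels[k] for k in ds.tree.clade_tip_indices(node)]
        df["clade_class"] = np.where(df["species"].isin(clade_species), "fish", "birds")
        table = TraitTable(df)
        spec = RegressionSpec(categorical={"clade_class": "birds"})
        reports = detect_heritable_shifts(
            summarize_branch_rates(tr, ds.tree), tr, ds.tree, include_single_branch=True
        )
        out = flag_mean_shift(reports[0], table, ds.tree, tr, spec)
        assert out.kind == "single-branch"  # evaluation skipped, not relabelled


class TestScaledTreeAndPathwise:
    def test_identity_scaling(self, trace_factory, three_tip_tree):
        tr = trace_factory(three_tip_tree, np.ones((4, three_tip_tree.n_branches)))
        scaled = median_scaled_tree(tr, three_tip_tree)
        assert np.allclose(scaled.lengths, three_tip_tree.lengths)

    def test_median_two_scales_branch(self, trace_factory):
        t = parse_newick("((x:3,y:1):2,z:5):0;")
        r = np.ones((4, t.n_branches))
        node_x = t._node_of_label["x"]
        r[:, node_x - 1] = [2.0, 2.0, 2.0, 2.0]
        scaled = median_scaled_tree(trace_factory(t, r), t)
        assert scaled.lengths[node_x] == pytest.approx(6.0)

    def test_scaled_depths_match_recomputation(self, trace_factory):
        t = simulate_tree(SimulationConfig(n_tips=20, seed=2))
        rng = np.random.default_rng(5)
        r = np.exp(rng.normal(0, 0.4, size=(31, t.n_branches)))
        scaled = median_scaled_tree(trace_factory(t, r), t)
        med = np.median(r, axis=0)
        sets = t.branch_tip_sets()
        for k, lab in enumerate(t.tip_labels):
            expect = sum(
                t.lengths[node] * med[node - 1]
                for node in range(1, t.n_nodes)
                if k in sets[node]
            )
            assert scaled.tip_depths()[lab] == pytest.approx(expect, abs=1e-10)

    def test_pathwise_all_one_is_depth(self, trace_factory):
        t = simulate_tree(SimulationConfig(n_tips=10, seed=3))
        tr = trace_factory(t, np.ones((5, t.n_branches)))
        pwr = pathwise_rates(tr, t)
        assert np.allclose(pwr.draws.to_numpy(), 1.0)  # unit-height tree

    def test_pathwise_arithmetic(self, trace_factory):
        t = parse_newick("((x:3,y:1):2,z:5):0;")
        r = np.ones((1, t.n_branches))
        inner = t.mrca(("x", "y"))
        node_x = t._node_of_label["x"]
        r[0, inner - 1] = 2.0  # branch of length 2 scaled x2
        r[0, node_x - 1] = 1.0  # branch of length 3 unscaled
        pwr = pathwise_rates(trace_factory(t, r), t)
        assert pwr.draws["x"].iloc[0] == pytest.approx(7.0)

    def test_median_of_sums_not_sum_of_medians(self, trace_factory):
        t = parse_newick("((x:1,y:1):1,z:2):0;")
        inner = t.mrca(("x", "y"))
        node_x = t._node_of_label["x"]
        r = np.ones((3, t.n_branches))
        r[:, inner - 1] = [2.0, 1.0, 1.0]
        r[:, node_x - 1] = [1.0, 2.0, 1.0]
        pwr = pathwise_rates(trace_factory(t, r), t)
        med = np.median(t.lengths[inner] * r[:, inner - 1] + t.lengths[node_x] * r[:, node_x - 1])
        assert pwr.median["x"] == pytest.approx(med) == 3.0
        sum_of_medians = float(
            np.median(r[:, inner - 1]) * t.lengths[inner]
            + np.median(r[:, node_x - 1]) * t.lengths[node_x]
        )
        assert sum_of_medians == 2.0  # the two summaries genuinely differ
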