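"""Posterior post-processing: branch rates, shifts, scaled trees, path-wise rates.

Branch classification follows the posterior-fraction rule: a branch is a rate
*increase* iff ``r > 1`` in strictly more than 50% of posterior samples, a
*decrease* iff ``r < 1`` in strictly more than 50%, and *background*
otherwise (a tie at exactly 50% is background). The optimized per-branch
rate is ``sigma_v^2 = sigma_b^2 * r``; because ``sigma_b^2`` is shared
within an iteration, per-iteration comparisons of ``sigma_v^2`` between two
branches reduce to comparisons of their ``r`` draws.

A *heritable rate shift* is a clade whose stem branch differs in rate from
its ancestor branch in > 50% of samples (criterion 1) and all of whose
descendant branches inherit the new rate, i.e. none differs from the stem in
> 50% of samples (criterion 2). Clades of 10+ tips are heritable shifts;
2-9 tips are incipient shifts; single tips are single-species shifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gls import GlsFit, RegressionSpec, build_design, gls_fit, likelihood_ratio_test
from .traits import TraitTable
from .tree import Phylogeny
from .vr import PosteriorTrace

__all__ = [
    "BranchRateSummary",
    "ShiftReport",
    "PathwiseRates",
    "summarize_branch_rates",
    "detect_heritable_shifts",
    "flag_mean_shift",
    "median_scaled_tree",
    "pathwise_rates",
]

logger = logging.getLogger(__name__)


@dataclass
class BranchRateSummary:
    branch: int  # branch index; branch b is the edge above preorder node b+1
    node: int
    frac_gt1: float
    frac_lt1: float
    median_r: float
    classification: str  # 'background' | 'increase' | 'decrease'
    sigma_v2_draws: np.ndarray | None = None


@dataclass
class ShiftReport:
    shift_id: int
    anchor_branch: int
    anchor_node: int
    tips: list[str]
    size: int
    kind: str  # 'heritable' | 'incipient' | 'single-species' | 'single-branch' | 'mean-shift-candidate'
    direction: str  # 'increase' | 'decrease'
    stem_vs_ancestor_frac: float
    max_descendant_diff_frac: float
    mean_shift_offset: float | None = None
    mean_shift_p: float | None = None


@dataclass
class PathwiseRates:
    """Per-tip posterior draws of root-to-tip sums of rate-scaled branch lengths."""

    draws: pd.DataFrame  # (samples x tips)
    median: pd.Series
    mean: pd.Series
    mode: pd.Series

    def summary(self, which: str = "median") -> pd.Series:
        return {"median": self.median, "mean": self.mean, "mode": self.mode}[which]


def _check(trace: PosteriorTrace, tree: Phylogeny) -> None:
    if len(trace) == 0:
        raise ValueError("empty posterior trace")
    if trace.r.shape[1] != tree.n_branches:
        raise ValueError(
            f"trace has {trace.r.shape[1]} branches but tree has {tree.n_branches}"
        )


def summarize_branch_rates(trace: PosteriorTrace, tree: Phylogeny) -> list[BranchRateSummary]:
    """Posterior summary and classification for every branch."""
    _check(trace, tree)
    out = []
    r = trace.r
    sv2 = trace.sigma2[:, None] * r
    for b in range(tree.n_branches):
        gt = float(np.mean(r[:, b] > 1.0))
        lt = float(np.mean(r[:, b] < 1.0))
        if gt > 0.5:
            cls = "increase"
        elif lt > 0.5:
            cls = "decrease"
        else:
            cls = "background"
        out.append(
            BranchRateSummary(
                branch=b,
                node=b + 1,
                frac_gt1=gt,
                frac_lt1=lt,
                median_r=float(np.median(r[:, b])),
                classification=cls,
                sigma_v2_draws=sv2[:, b],
            )
        )
    return out


def _pairwise_fracs(r: np.ndarray, b: int, a: int | None) -> tuple[float, float]:
    """Fractions of iterations with r_b > r_a and r_b < r_a.

    ``a is None`` compares against the background scalar (exactly 1), which
    stands in for the non-existent branch above a child of the root.
    """
    ra = r[:, a] if a is not None else 1.0
    return float(np.mean(r[:, b] > ra)), float(np.mean(r[:, b] < ra))


def detect_heritable_shifts(
    summaries: list[BranchRateSummary],
    trace: PosteriorTrace,
    tree: Phylogeny,
    min_size: int = 10,
    include_single_branch: bool = False,
) -> list[ShiftReport]:
    """Find clades that inherit a wholescale rate change.

    Candidates are evaluated per the two posterior-fraction criteria; where a
    clade and a nested subclade both qualify, the largest clade wins (the
    nested one is pruned). Children of the root are compared against the
    background rate since they have no ancestor branch.

    With ``include_single_branch=True``, internal branches that pass
    criterion 1 but whose rate elevation is *not* inherited (criterion 2
    fails and every descendant branch is classified background) are also
    reported, with kind ``single-branch``. These are the screening set for
    mean shifts: an intercept change in a clade's allometry shows up as a
    rate change confined to its stem branch (see :func:`flag_mean_shift`).
    """
    _check(trace, tree)
    r = trace.r
    candidates = []
    single_branch = []
    for b in range(tree.n_branches):
        node = b + 1
        # a shift's direction is the stem branch's own classification, so a
        # background-classified branch cannot anchor one (this also keeps
        # children of an isolated stem elevation from registering as
        # spurious "decreases" relative to their parent)
        direction = summaries[b].classification
        if direction == "background":
            continue
        parent_node = int(tree.parent[node])
        anc = parent_node - 1 if parent_node > 0 else None
        up, down = _pairwise_fracs(r, b, anc)
        stem_frac = max(up, down)
        if stem_frac <= 0.5:
            continue
        # criterion 2: no descendant branch differs from the stem
        desc = tree.clade_nodes(node)[1:] - 1  # descendant branches
        max_diff = 0.0
        ok = True
        for d in desc:
            du, dd = _pairwise_fracs(r, int(d), b)
            max_diff = max(max_diff, du, dd)
            if du > 0.5 or dd > 0.5:
                ok = False
                break
        tips_idx = tree.clade_tip_indices(node)
        entry = (b, node, direction, stem_frac, max_diff, [tree.tip_labels[k] for k in tips_idx])
        if ok:
            candidates.append(entry)
        elif (
            include_single_branch
            and not tree.is_tip(node)
            and all(summaries[int(d)].classification == "background" for d in desc)
        ):
            single_branch.append(entry)

    # largest clade wins: drop candidates nested inside another candidate
    anchors = {c[0] for c in candidates}
    reports: list[ShiftReport] = []
    for b, node, direction, stem_frac, max_diff, tips in sorted(
        candidates, key=lambda c: -len(c[5])
    ):
        nested = False
        v = int(tree.parent[node])
        while v > 0:
            if v - 1 in anchors and any(rep.anchor_branch == v - 1 for rep in reports):
                nested = True
                break
            v = int(tree.parent[v])
        if nested:
            continue
        size = len(tips)
        kind = "heritable" if size >= min_size else ("incipient" if size >= 2 else "single-species")
        reports.append(
            ShiftReport(
                shift_id=len(reports),
                anchor_branch=b,
                anchor_node=node,
                tips=tips,
                size=size,
                kind=kind,
                direction=direction,
                stem_vs_ancestor_frac=stem_frac,
                max_descendant_diff_frac=max_diff,
            )
        )
    for b, node, direction, stem_frac, max_diff, tips in single_branch:
        reports.append(
            ShiftReport(
                shift_id=len(reports),
                anchor_branch=b,
                anchor_node=node,
                tips=tips,
                size=len(tips),
                kind="single-branch",
                direction=direction,
                stem_vs_ancestor_frac=stem_frac,
                max_descendant_diff_frac=max_diff,
            )
        )
    return reports


def flag_mean_shift(
    shift: ShiftReport,
    table: TraitTable,
    tree: Phylogeny,
    trace: PosteriorTrace,
    spec: RegressionSpec | None = None,
    alpha: float = 0.05,
) -> ShiftReport:
    """Test whether a rate shift is better explained by an intercept change.

    Fits the allometric regression on the ORIGINAL time tree with and without
    a clade-membership intercept dummy. If the dummy is significant (LRT
    p < alpha) and the elevated rate is confined to the anchor branch (all
    descendant branches classified background), the shift is re-labelled a
    mean-shift candidate and the offset sign recorded.
    """
    spec = spec or RegressionSpec()
    node = shift.anchor_node
    if tree.is_tip(node):
        raise ValueError("mean-shift diagnosis needs an internal anchor branch")
    df = table.reindex_to(tree.tip_labels)
    X, y = build_design(spec, df)
    in_clade = np.zeros(len(df))
    in_clade[tree.clade_tip_indices(node)] = 1.0
    if len(df) < X.shape[1] + 3:
        logger.info("clade too small for mean-shift evaluation; skipped")
        return shift
    Xd = X.copy()
    Xd["clade_dummy"] = in_clade
    from .gls import PhyloGLS

    try:
        full = PhyloGLS(tree=tree).fit(Xd, y)
        nested = PhyloGLS(tree=tree).fit(X, y)
    except ValueError as exc:
        logger.info("mean-shift evaluation skipped: %s", exc)
        return shift
    D = 2.0 * (full.loglik_ - nested.loglik_)
    from scipy import stats

    p = float(stats.chi2.sf(max(D, 0.0), 1))
    offset = float(full.coefs_[-1])

    summaries = summarize_branch_rates(trace, tree)
    desc = tree.clade_nodes(node)[1:] - 1
    descendants_background = all(summaries[int(d)].classification == "background" for d in desc)

    if p < alpha and descendants_background:
        return ShiftReport(
            shift_id=shift.shift_id,
            anchor_branch=shift.anchor_branch,
            anchor_node=shift.anchor_node,
            tips=shift.tips,
            size=shift.size,
            kind="mean-shift-candidate",
            direction=shift.direction,
            stem_vs_ancestor_frac=shift.stem_vs_ancestor_frac,
            max_descendant_diff_frac=shift.max_descendant_diff_frac,
            mean_shift_offset=offset,
            mean_shift_p=p,
        )
    shift.mean_shift_offset = offset
    shift.mean_shift_p = p
    return shift


def median_scaled_tree(trace: PosteriorTrace, tree: Phylogeny) -> Phylogeny:
    """Tree with each branch length multiplied by its posterior median scalar."""
    _check(trace, tree)
    med = np.median(trace.r, axis=0)
    return tree.scaled_by(med)


def pathwise_rates(trace: PosteriorTrace, tree: Phylogeny) -> PathwiseRates:
    """Per-tip, per-draw sums of rate-scaled branch lengths along root-to-tip paths.

    The summaries are medians/means/modes of the per-draw path sums — not
    path sums over a summary tree; the two differ whenever scalars are
    correlated along a path.
    """
    _check(trace, tree)
    B = tree.n_branches
    lengths = tree.lengths[1:]
    # path membership: P[b, t] = l_b if branch b lies on the path to tip t
    member = np.zeros((B, tree.n_tips))
    sets = tree.branch_tip_sets()
    for b in range(B):
        member[b, sets[b + 1]] = lengths[b]
    # the (unscaled) root edge contributes to every path
    draws = trace.r @ member + float(tree.lengths[0])  # (S, n_tips)
    df = pd.DataFrame(draws, columns=tree.tip_labels)
    med = df.median(axis=0)
    mean = df.mean(axis=0)
    # mode via a histogram peak (posterior draws are continuous)
    modes = {}
    for c in df.columns:
        vals = df[c].to_numpy()
        if np.ptp(vals) < 1e-9 * max(1.0, abs(float(vals.mean()))):
            modes[c] = float(np.median(vals))
            continue
        hist, edges = np.histogram(vals, bins=max(10, len(vals) // 50))
        k = int(np.argmax(hist))
        modes[c] = 0.5 * (edges[k] + edges[k + 1])
    return PathwiseRates(draws=df, median=med, mean=mean, mode=pd.Series(modes))
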