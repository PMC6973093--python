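"""Synthetic trees and trait data with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a birth-death time tree; a log10-log10 testes-body allometry with
class-specific slopes and intercepts; phylogenetically structured Brownian
residuals with background variance sigma_b^2; planted clade-level rate
shifts (variance scalars inherited by every branch of a clade, or intercept
offsets for mean shifts); and planted directional trends in which residual
trait values covary with accumulated path-wise rate inside one mating-system
category.

Trees are rescaled to unit root-to-tip height by default, so sigma_b^2 is
the residual variance accumulated from root to tip and planted trend
coefficients are per unit path-wise rate.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from dendropy.model import birthdeath
from scipy import linalg

from .gls import phylo_covariance
from .traits import CLASS_LEVELS, MATING_SYSTEM_LEVELS, TraitTable
from .tree import Phylogeny, normalize_label

__all__ = [
    "ShiftSpec",
    "TrendSpec",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_tree",
    "simulate_traits",
    "plant_directional_trend",
    "simulate_dataset",
    "find_clade",
    "find_disjoint_clades",
]


def find_clade(
    tree: Phylogeny,
    min_size: int,
    max_size: int | None = None,
    min_stem: float = 0.0,
) -> tuple[str, str]:
    """Anchor tips of a clade whose size falls in [min_size, max_size].

    Returns two tip labels whose MRCA subtends the clade (the form shift
    anchors take). Among qualifying clades, the one with the longest stem
    branch is preferred, and ``min_stem`` can require a minimum stem length
    (as a fraction of the tree depth scale): a shift planted above a
    near-zero-length stem is not a clade-level event at all — the stem
    contributes essentially no displacement, so not even unlimited data
    could localize it — and such anchors make a meaningless test bed for
    shift detection. When no clade in the size window has a long-enough
    stem, the window widens by up to three tips before giving up.
    """
    max_size = max_size if max_size is not None else min_size
    best = None
    for widen in range(4):
        for v in range(1, tree.n_nodes):
            if tree.is_tip(v):
                continue
            tips = tree.clade_tip_indices(v)
            stem = float(tree.lengths[v])
            if (
                min_size <= tips.size <= max_size + widen
                and stem >= min_stem
                and (best is None or stem > best[0])
            ):
                best = (stem, v, tips)
        if best is not None:
            break
    if best is None:
        raise ValueError(f"no clade of size in [{min_size}, {max_size}] exists in this tree")
    _, v, tips = best
    labels = [tree.tip_labels[k] for k in tips]
    # verify the two anchors reconstruct the same clade
    assert tree.mrca((labels[0], labels[-1])) == v
    return labels[0], labels[-1]


def find_disjoint_clades(
    tree: Phylogeny, sizes: list[tuple[int, int]]
) -> list[tuple[str, str]]:
    """Anchors for mutually disjoint clades with the requested size ranges.

    Greedy: clades are chosen longest-stem-first within each size range,
    skipping any clade overlapping an earlier choice. Raises if a range
    cannot be satisfied.
    """
    taken: set[int] = set()
    anchors = []
    for lo, hi in sizes:
        cands = []
        for v in range(1, tree.n_nodes):
            if tree.is_tip(v):
                continue
            tips = tree.clade_tip_indices(v)
            if lo <= tips.size <= hi and not (set(tips.tolist()) & taken):
                cands.append((float(tree.lengths[v]), v, tips))
        if not cands:
            raise ValueError(f"no disjoint clade of size in [{lo}, {hi}] available")
        _, v, tips = max(cands)
        taken |= set(tips.tolist())
        labels = [tree.tip_labels[k] for k in tips]
        anchors.append((labels[0], labels[-1]))
    return anchors


@dataclass(frozen=True)
class ShiftSpec:
    """A planted clade-level shift, anchored at the MRCA of two tips.

    ``kind='variance'`` multiplies the branch-length rate scalar of the stem
    branch and every descendant branch by ``multiplier`` (a heritable rate
    shift). ``kind='mean'`` adds ``mean_offset`` to the response of every tip
    in the clade (an intercept shift, which the rate model sees as a rate
    increase on the stem branch only).
    """

    anchor: tuple[str, str]
    multiplier: float = 1.0
    kind: str = "variance"
    mean_offset: float = 0.0

    def __post_init__(self):
        if self.kind not in ("variance", "mean"):
            raise ValueError(f"unknown shift kind {self.kind!r}")
        if self.multiplier <= 0:
            raise ValueError("shift multiplier must be > 0")


@dataclass(frozen=True)
class TrendSpec:
    """A directional trend: within ``category``, the response gains
    ``coefficient`` x (path-wise rate - category mean path-wise rate)."""

    category: str
    coefficient: float


@dataclass
class SimulationConfig:
    n_tips: int = 100
    birth_rate: float = 1.0
    death_rate: float = 0.0
    #: per-class allometric coefficients (log10 g testes vs log10 g body)
    intercepts: dict[str, float] = field(default_factory=lambda: {"birds": -2.0})
    slopes: dict[str, float] = field(default_factory=lambda: {"birds": 0.67})
    #: background Brownian variance of the regression residual, trait^2 per
    #: unit of (unit-height) tree depth
    sigma2_b: float = 0.05
    shifts: tuple[ShiftSpec, ...] = ()
    trend: TrendSpec | None = None
    #: multinomial mating-system frequencies per class
    mating_frequencies: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"birds": {"monogamy": 0.75, "polygyny": 0.15, "polyandry": 0.10}}
    )
    #: 'iid' draws mating systems independently per tip; 'blocks' assigns
    #: contiguous blocks in tree order, mimicking phylogenetic clustering
    mating_assignment: str = "iid"
    #: body-mass generator: 'bm' = Brownian motion on the tree (phylogenetic
    #: signal in the predictor, the default), 'iid' = independent normals
    body_mode: str = "bm"
    body_mean: float = 2.5
    sigma2_body: float = 0.5
    #: rescale the simulated tree to this root-to-tip height (None keeps the
    #: raw birth-death depth)
    tree_height: float | None = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")
        if self.birth_rate < 0 or self.death_rate < 0:
            raise ValueError("birth and death rates must be >= 0")
        if set(self.intercepts) != set(self.slopes):
            raise ValueError("intercepts and slopes must cover the same classes")
        unknown = set(self.intercepts) - set(CLASS_LEVELS)
        if unknown:
            raise ValueError(f"unknown taxonomic classes: {sorted(unknown)}")
        for cls, freqs in self.mating_frequencies.items():
            tot = sum(freqs.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"mating-system frequencies for {cls!r} sum to {tot}, not 1")
            bad = set(freqs) - set(MATING_SYSTEM_LEVELS)
            if bad:
                raise ValueError(f"unknown mating systems: {sorted(bad)}")
        if self.body_mode not in ("bm", "iid"):
            raise ValueError("body_mode must be 'bm' or 'iid'")
        if self.mating_assignment not in ("iid", "blocks"):
            raise ValueError("mating_assignment must be 'iid' or 'blocks'")

    @property
    def classes(self) -> list[str]:
        return list(self.intercepts)


@dataclass
class SimulatedDataset:
    """Generated data plus the ground truth behind it."""

    tree: Phylogeny
    table: TraitTable
    #: true per-branch rate multipliers (length n_branches, branch b = node b+1)
    branch_scalars: np.ndarray
    #: the tree with branch lengths multiplied by the true scalars
    scaled_tree: Phylogeny
    #: true path-wise rate per tip (root-to-tip sum of scaled branch lengths)
    pathwise_rates: pd.Series
    config: SimulationConfig


# ---------------------------------------------------------------------------


def simulate_tree(cfg: SimulationConfig, max_retries: int = 100) -> Phylogeny:
    """Birth-death tree conditioned on ``cfg.n_tips`` surviving tips.

    Deterministic under a fixed seed; tips relabelled s1..sN in preorder.
    """
    rng = random.Random(cfg.seed)
    last_err: Exception | None = None
    for _ in range(max_retries):
        try:
            # GSA sampling: draw the tree from a uniformly chosen moment while
            # exactly n_tips lineages are extant, so terminal branches have
            # positive length (plain conditioning stops at the n-th birth and
            # yields zero-length cherries, a singular trait covariance)
            dtree = birthdeath.birth_death_tree(
                birth_rate=cfg.birth_rate,
                death_rate=cfg.death_rate,
                num_extant_tips=cfg.n_tips,
                gsa_ntax=2 * cfg.n_tips,
                rng=rng,
            )
            break
        except Exception as exc:  # total extinction; retry with advanced rng
            last_err = exc
    else:
        raise RuntimeError(f"birth-death simulation failed after {max_retries} attempts: {last_err}")
    tree = Phylogeny.from_dendropy(dtree)
    # relabel tips deterministically in node order
    labels: list[str | None] = [None] * tree.n_nodes
    for k, i in enumerate(tree.tip_ids, start=1):
        labels[i] = f"s{k}"
    lengths = tree.lengths.copy()
    lengths[0] = 0.0  # drop the origin (root edge) time
    tree = Phylogeny(tree.parent, lengths, labels)
    if cfg.tree_height is not None:
        depth = tree.node_depths()[tree.tip_ids].max()
        tree = tree.with_lengths(tree.lengths * (cfg.tree_height / depth))
    return tree


def true_branch_scalars(tree: Phylogeny, cfg: SimulationConfig) -> np.ndarray:
    """Per-branch multipliers implied by the planted variance shifts."""
    scalars = np.ones(tree.n_branches)
    for shift in cfg.shifts:
        if shift.kind != "variance":
            continue
        node = tree.mrca(shift.anchor)
        if node == 0:
            raise ValueError(f"shift anchor {shift.anchor} spans the whole tree (MRCA is the root)")
        for v in tree.clade_nodes(node):
            scalars[v - 1] *= shift.multiplier
    return scalars


def _assign_classes(tree: Phylogeny, classes: list[str]) -> pd.Series:
    """Partition tips into len(classes) clade blocks (largest-clade splitting)."""
    if len(classes) == 1:
        return pd.Series(classes[0], index=tree.tip_labels)
    # repeatedly split the largest block at its root's children
    blocks: list[list[int]] = [[0]]

    def block_tips(block: list[int]) -> list[int]:
        out: list[int] = []
        for v in block:
            out.extend(tree.clade_tip_indices(v).tolist())
        return out

    while len(blocks) < len(classes):
        sizes = [len(block_tips(b)) for b in blocks]
        k = int(np.argmax(sizes))
        block = blocks.pop(k)
        # split the node with the most tips into its children
        node_sizes = [(len(tree.clade_tip_indices(v)), v) for v in block]
        _, v = max(node_sizes)
        rest = [u for u in block if u != v]
        kids = tree.children[v]
        blocks.append(rest + [kids[0]])
        blocks.append(list(kids[1:]))
    assign = pd.Series("", index=tree.tip_labels, dtype=object)
    for cls, block in zip(classes, blocks):
        for k in block_tips(block):
            assign.iloc[k] = cls
    return assign


def simulate_traits(tree: Phylogeny, cfg: SimulationConfig) -> TraitTable:
    """Simulate the trait table on ``tree`` under the planted model."""
    ds = _simulate(tree, cfg)
    return ds.table


def _simulate(tree: Phylogeny, cfg: SimulationConfig) -> SimulatedDataset:
    if tree.n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = np.random.default_rng(cfg.seed + 1)
    n = tree.n_tips
    labels = tree.tip_labels

    V = phylo_covariance(tree)
    scalars = true_branch_scalars(tree, cfg)
    scaled = tree.scaled_by(scalars)
    Vs = phylo_covariance(scaled)

    classes = _assign_classes(tree, cfg.classes)

    # body mass predictor
    if cfg.body_mode == "bm":
        Lb = _chol(V)
        body = cfg.body_mean + np.sqrt(cfg.sigma2_body) * (Lb @ rng.standard_normal(n))
    else:
        body = cfg.body_mean + np.sqrt(cfg.sigma2_body) * rng.standard_normal(n)

    # response: class-specific allometry + phylogenetic residual on scaled tree
    mu = np.array([cfg.intercepts[classes.iloc[i]] for i in range(n)]) + np.array(
        [cfg.slopes[classes.iloc[i]] for i in range(n)]
    ) * body
    L = _chol(cfg.sigma2_b * Vs) if cfg.sigma2_b > 0 else None
    resid = L @ rng.standard_normal(n) if L is not None else np.zeros(n)
    y = mu + resid

    # mean-type shifts: clade-wide intercept offsets
    for shift in cfg.shifts:
        if shift.kind == "mean":
            node = tree.mrca(shift.anchor)
            y[tree.clade_tip_indices(node)] += shift.mean_offset

    # mating systems
    ms = pd.Series([pd.NA] * n, index=labels, dtype=object)
    for cls, freqs in cfg.mating_frequencies.items():
        members = np.nonzero((classes == cls).to_numpy())[0]
        if members.size == 0:
            continue
        levels = list(freqs)
        probs = np.array([freqs[l] for l in levels])
        if cfg.mating_assignment == "iid":
            draws = rng.choice(len(levels), size=members.size, p=probs)
        else:  # contiguous blocks in tree tip order ~ phylogenetic clustering
            counts = np.floor(probs * members.size).astype(int)
            while counts.sum() < members.size:
                counts[int(np.argmax(probs * members.size - counts))] += 1
            draws = np.repeat(np.arange(len(levels)), counts)
        for k, d in zip(members, draws):
            ms.iloc[k] = levels[d]

    df = pd.DataFrame(
        {
            "species": labels,
            "log_testes": y,
            "log_body": body,
            "clade_class": classes.to_numpy(),
            "mating_system": ms.to_numpy(),
        }
    )
    table = TraitTable(df)

    pwr = pd.Series(scaled.node_depths()[scaled.tip_ids], index=labels, name="pathwise_rate")
    ds = SimulatedDataset(
        tree=tree,
        table=table,
        branch_scalars=scalars,
        scaled_tree=scaled,
        pathwise_rates=pwr,
        config=cfg,
    )
    if cfg.trend is not None:
        ds = replace(ds, table=plant_directional_trend(ds.table, tree, cfg))
    return ds


def plant_directional_trend(
    table: TraitTable, tree: Phylogeny, cfg: SimulationConfig
) -> TraitTable:
    """Add the configured path-wise-rate trend to one mating-system category.

    For tips in ``cfg.trend.category`` the response is shifted by
    ``coefficient x (true path-wise rate - mean path-wise rate over all
    tips)``; centring on the global mean keeps the offsets interpretable as
    deviations from an average-history species (and still applies to a
    category with a single member). Requires the planted variance shifts
    (they are what makes path-wise rates vary across tips).
    """
    if cfg.trend is None:
        return table
    scalars = true_branch_scalars(tree, cfg)
    scaled = tree.scaled_by(scalars)
    pwr = pd.Series(
        scaled.node_depths()[scaled.tip_ids],
        index=[normalize_label(l) for l in tree.tip_labels],
    )
    df = table.data.copy()
    mask = (df["mating_system"] == cfg.trend.category).to_numpy()
    if not mask.any():
        raise ValueError(f"category {cfg.trend.category!r} absent from the table")
    rates = pwr.loc[df.loc[mask, "species"]].to_numpy()
    df.loc[mask, "log_testes"] += cfg.trend.coefficient * (rates - pwr.mean())
    return TraitTable(df, table.ms_levels, table.class_levels, table.rejected)


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Tree + traits + ground truth in one call (the main entry point)."""
    tree = simulate_tree(cfg)
    return _simulate(tree, cfg)


def _chol(V: np.ndarray) -> np.ndarray:
    try:
        return linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("singular trait covariance (duplicate zero-length tips?)") from exc
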