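"""The variable-rates regression model: Bayesian MCMC over branch rate scalars.

Model
-----
Within a phylogenetic GLS regression ``y = X beta + eps``, the residual
``eps`` evolves by Brownian motion with background variance ``sigma_b^2``
along a tree whose branch lengths (in time) are each multiplied by a
non-negative scalar ``r``:

    eps ~ MVN(0, sigma_b^2 * V(r)),   V(r)[i,j] = sum of l_b * r_b over
                                      branches b shared by tips i and j.

Branches with ``r > 1`` evolve faster than background, ``r < 1`` slower.

Prior: copy-or-innovate rate inheritance
----------------------------------------
Each branch independently either *innovates* — with probability ``p_active``
it starts a new rate deviation, drawing ``log r`` from a normal prior — or
*inherits* its parent branch's effective scalar exactly. Branches with no
innovating ancestor therefore sit at the background rate, ``r == 1``
exactly, and a single innovation propagates to the whole clade below it
until overridden by a deeper innovation. This is how heritable rate shifts
arise in the model: a clade-wide shift is one innovation, its descendants
share the new rate exactly, and the posterior fraction tests used downstream
("r > 1 in more than 50% of samples"; "descendants do not differ from the
stem") are well-defined without density estimation.

A reversible-jump move toggles a branch's innovation indicator (innovation
values proposed from their prior, so the acceptance ratio reduces to the
likelihood ratio times the Bernoulli odds), and a random-walk move perturbs
one innovation's value. ``beta`` has independent wide normal priors;
``sigma_b^2`` a half-Cauchy on the standard-deviation scale.

Note the deliberate scale confound: multiplying every ``r`` by ``c`` while
dividing ``sigma_b^2`` by ``c`` leaves the likelihood unchanged.
Identifiability is imposed only by the prior (non-innovating root-level
branches pinned at ``r = 1``; innovations pulled toward ``r = 1``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator

from .gls import PhyloGLS, RegressionSpec, build_design
from .traits import TraitTable
from .tree import Phylogeny

__all__ = [
    "VariableRatesPriors",
    "ProposalSettings",
    "ChainSettings",
    "VRPosteriorSample",
    "PosteriorTrace",
    "VariableRatesSampler",
    "VariableRatesRegression",
    "run_chain",
    "run_chains",
    "vr_loglik",
    "mcmc_step",
    "compute_px",
    "compute_px_diff",
    "effective_sample_size",
]

LOG2PI = math.log(2.0 * math.pi)


def _normal_logpdf(x: float, mu: float, sd: float) -> float:
    return -0.5 * ((x - mu) / sd) ** 2 - 0.5 * LOG2PI - math.log(sd)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class VariableRatesPriors:
    """Priors of the variable-rates model.

    ``p_active`` is the innovation probability per branch (expected fraction
    of branches starting a new rate deviation); ``log_r_scale`` the standard
    deviation of the normal prior on an innovation's ``log r``;
    ``beta_scale`` the standard deviation of the normal priors on regression
    coefficients; ``sigma_scale`` the half-Cauchy scale on ``sigma_b``.
    """

    beta_scale: float = 10.0
    sigma_scale: float = 1.0
    p_active: float = 0.05
    log_r_scale: float = 1.5

    def __post_init__(self):
        if not 0 < self.p_active < 1:
            raise ValueError("p_active must be in (0, 1)")
        if self.log_r_scale <= 0 or self.beta_scale <= 0 or self.sigma_scale <= 0:
            raise ValueError("prior scales must be positive")


@dataclass(frozen=True)
class ProposalSettings:
    beta_step: float | None = None  # None: 2.4 x GLS standard errors
    sigma_step: float = 0.5
    log_r_step: float = 0.6
    #: sd of the child-value proposals in the stem-isolation move
    stem_child_step: float = 0.3
    #: relative frequencies of elementary moves: per regression coefficient /
    #: sigma_b^2 / innovation toggle (RJ) / innovation-value walk /
    #: stem-isolation compound move / innovation slide to a neighbour branch
    w_beta: float = 1.0
    w_sigma: float = 1.0
    w_rj: float = 4.0
    w_scalar: float = 3.0
    w_stem: float = 1.0
    w_slide: float = 2.0


@dataclass(frozen=True)
class ChainSettings:
    """One iteration is one elementary Metropolis-Hastings proposal."""

    iterations: int = 200_000
    burn_in: int = 50_000
    thin: int = 20
    seed: int = 0
    priors: VariableRatesPriors = field(default_factory=VariableRatesPriors)
    proposals: ProposalSettings = field(default_factory=ProposalSettings)

    def __post_init__(self):
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class VRPosteriorSample:
    """One posterior draw of the variable-rates regression."""

    beta: np.ndarray
    sigma2: float
    r: np.ndarray  # per-branch effective scalars; branch b <-> preorder node b+1
    loglik: float
    iteration: int = -1


@dataclass
class PosteriorTrace:
    """Thinned post-burn-in samples of the variable-rates model.

    Branch ordering is fixed across all samples: column ``b`` of ``r`` is the
    branch above preorder node ``b + 1`` of ``tree``.
    """

    beta: np.ndarray  # (S, p)
    sigma2: np.ndarray  # (S,)
    r: np.ndarray  # (S, B) effective scalars
    loglik: np.ndarray  # (S,)
    coef_names: list[str]
    tree: Phylogeny
    settings: ChainSettings
    n_innovations: np.ndarray | None = None  # (S,)
    ess: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return self.beta.shape[0]

    @property
    def n_active(self) -> np.ndarray:
        if self.n_innovations is not None:
            return self.n_innovations
        return np.sum(self.r != 1.0, axis=1)

    def sample(self, i: int) -> VRPosteriorSample:
        return VRPosteriorSample(
            beta=self.beta[i],
            sigma2=float(self.sigma2[i]),
            r=self.r[i],
            loglik=float(self.loglik[i]),
            iteration=i,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.beta, columns=self.coef_names)
        df["sigma2_b"] = self.sigma2
        df["loglik"] = self.loglik
        df["n_active"] = self.n_active
        return df


# ---------------------------------------------------------------------------
# the sampler


class VariableRatesSampler:
    """MCMC kernel for the (optionally tempered) variable-rates posterior.

    ``power`` tempers the likelihood: the invariant density is
    ``prior x likelihood^power`` (power 1 = posterior, power 0 = prior), as
    required by stepping-stone marginal-likelihood estimation.

    With ``variable_rates=False`` the scalar machinery is frozen at r = 1
    and the kernel samples the single-rate model m0.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        tree: Phylogeny,
        priors: VariableRatesPriors | None = None,
        proposals: ProposalSettings | None = None,
        variable_rates: bool = True,
        power: float = 1.0,
        likelihood_off: bool = False,
        coef_names: list[str] | None = None,
    ):
        self.priors = priors or VariableRatesPriors()
        self.proposals = proposals or ProposalSettings()
        self.variable_rates = variable_rates
        self.power = power
        self.likelihood_off = likelihood_off

        y = np.asarray(y, float).ravel()
        X = np.asarray(X, float)
        n = y.shape[0]
        if X.shape[0] != n:
            raise ValueError("X and y row mismatch")
        X = np.column_stack([np.ones(n), X])
        self.X, self.y, self.n, self.p = X, y, n, X.shape[1]
        self.coef_names = ["(intercept)"] + (
            coef_names or [f"x{i}" for i in range(X.shape[1] - 1)]
        )
        if len(self.coef_names) != self.p:
            raise ValueError("coef_names length mismatch")
        if n != tree.n_tips:
            raise ValueError("data rows must match tree tips (ordered like tree.tip_labels)")

        self.tree = tree
        self.B = tree.n_branches
        self.lengths = tree.lengths[1:]  # branch b <-> node b+1
        sets = tree.branch_tip_sets()
        self.tip_sets = [sets[node] for node in range(1, tree.n_nodes)]
        self.parent_branch = np.array(
            [tree.parent[node] - 1 for node in range(1, tree.n_nodes)], dtype=np.intp
        )  # -1 where the parent is the root
        self.child_branches = [
            np.array([c - 1 for c in tree.children[node]], dtype=np.intp)
            for node in range(1, tree.n_nodes)
        ]
        self.internal_branches = np.array(
            [b for b in range(self.B) if len(self.child_branches[b]) > 0], dtype=np.intp
        )

        # reference GLS fit: initialization + default beta proposal scale
        ref = PhyloGLS(tree=tree).fit(X[:, 1:], y)
        self._ref = ref
        step = self.proposals.beta_step
        self.beta_steps = (
            np.full(self.p, float(step)) if step is not None else 2.4 * ref.se_
        )

        pr = self.proposals
        w = np.array(
            [
                pr.w_beta * self.p,
                pr.w_sigma,
                pr.w_rj if variable_rates else 0.0,
                pr.w_scalar if variable_rates else 0.0,
                pr.w_stem if variable_rates and self.internal_branches.size else 0.0,
                pr.w_slide if variable_rates else 0.0,
            ]
        )
        self.move_probs = w / w.sum()
        self.n_accept = 0
        self.n_propose = 0

    # -- priors ------------------------------------------------------------

    def _log_prior_logs2(self, x: float) -> float:
        # half-Cauchy(scale s) on sigma = exp(x/2), with the Jacobian to x
        s = self.priors.sigma_scale
        sig = math.exp(0.5 * x)
        return math.log(2.0 / (math.pi * s * (1.0 + sig**2 / s**2))) + math.log(sig / 2.0)

    def _log_prior_value(self, v: float) -> float:
        s = self.priors.log_r_scale
        return -0.5 * (v / s) ** 2 - 0.5 * LOG2PI - math.log(s)

    # -- inheritance bookkeeping -------------------------------------------

    def _domain(self, st: "_State", b: int) -> list[int]:
        """Branch b and its non-innovating descendants (b's inheritance domain)."""
        out = [b]
        stack = [c for c in self.child_branches[b]]
        while stack:
            c = int(stack.pop())
            if st.innov[c]:
                continue
            out.append(c)
            stack.extend(self.child_branches[c])
        return out

    # -- likelihood caches ---------------------------------------------------

    def _build_caches(self, st: "_State") -> None:
        if self.likelihood_off:
            st.loglik = 0.0
            return
        w = self.lengths * np.exp(st.eff)
        n = self.n
        # root edge: shared, un-scaled path for every tip (usually zero)
        V = np.full((n, n), float(self.tree.lengths[0]))
        for b in range(self.B):
            if w[b] == 0.0:
                continue
            s = self.tip_sets[b]
            V[np.ix_(s, s)] += w[b]
        st.V = V
        try:
            st.L = linalg.cholesky(V, lower=True)
        except linalg.LinAlgError as exc:
            raise FloatingPointError(
                "singular scaled-tree covariance (a tip has an all-zero path)"
            ) from exc
        st.logdet = 2.0 * float(np.sum(np.log(np.diag(st.L))))
        st.Zx = linalg.solve_triangular(st.L, self.X, lower=True)
        st.zy = linalg.solve_triangular(st.L, self.y, lower=True)
        st.m = st.zy - st.Zx @ st.beta
        st.quad = float(st.m @ st.m)
        st.loglik = self._ll(st.logdet, st.quad, st.log_s2)

    def _ll(self, logdet: float, quad: float, log_s2: float) -> float:
        n = self.n
        return -0.5 * (n * LOG2PI + n * log_s2 + logdet + quad * math.exp(-log_s2))

    # -- state -------------------------------------------------------------

    def init_state(self, rng: np.random.Generator) -> "_State":
        st = _State(
            beta=self._ref.coefs_.copy(),
            log_s2=math.log(max(self._ref.sigma2_, 1e-12)),
            innov=np.zeros(self.B, dtype=bool),
            val=np.zeros(self.B),
            eff=np.zeros(self.B),
        )
        self._build_caches(st)
        if not np.isfinite(st.loglik):
            raise FloatingPointError("non-finite likelihood at initialization")
        return st

    def loglik(self, st: "_State") -> float:
        return st.loglik

    # -- elementary moves ----------------------------------------------------

    def step(self, st: "_State", rng: np.random.Generator) -> "_State":
        """One elementary MH proposal (in place); returns the state."""
        kind = rng.choice(6, p=self.move_probs)
        self.n_propose += 1
        if kind == 0:
            self._move_beta(st, rng)
        elif kind == 1:
            self._move_sigma(st, rng)
        elif kind == 2:
            self._move_rj(st, rng)
        elif kind == 3:
            self._move_value(st, rng)
        elif kind == 4:
            self._move_stem_isolation(st, rng)
        else:
            self._move_slide(st, rng)
        return st

    def _accept(self, rng, log_ratio: float) -> bool:
        ok = log_ratio >= 0.0 or math.log(rng.random()) < log_ratio
        if ok:
            self.n_accept += 1
        return ok

    def _move_beta(self, st, rng) -> None:
        j = int(rng.integers(self.p))
        delta = float(rng.normal(0.0, self.beta_steps[j]))
        bj_new = st.beta[j] + delta
        dprior = -0.5 * (bj_new**2 - st.beta[j] ** 2) / self.priors.beta_scale**2
        if self.likelihood_off:
            dll = 0.0
        else:
            m_new = st.m - st.Zx[:, j] * delta
            quad_new = float(m_new @ m_new)
            dll = -0.5 * (quad_new - st.quad) * math.exp(-st.log_s2)
        if self._accept(rng, self.power * dll + dprior):
            st.beta[j] = bj_new
            if not self.likelihood_off:
                st.m = m_new
                st.quad = quad_new
                st.loglik += dll

    def _move_sigma(self, st, rng) -> None:
        x_new = st.log_s2 + float(rng.normal(0.0, self.proposals.sigma_step))
        dprior = self._log_prior_logs2(x_new) - self._log_prior_logs2(st.log_s2)
        if self.likelihood_off:
            dll = 0.0
        else:
            ll_new = self._ll(st.logdet, st.quad, x_new)
            dll = ll_new - st.loglik
        if self._accept(rng, self.power * dll + dprior):
            st.log_s2 = x_new
            if not self.likelihood_off:
                st.loglik += dll

    def _eff_change(self, st, domain: list[int], new_eff: float):
        """Candidate caches when every branch in ``domain`` moves to ``new_eff``."""
        return self._eff_change_multi(st, [(domain, new_eff)])

    def _eff_change_multi(self, st, changes: list[tuple[list[int], float]]):
        """Candidate caches for several disjoint (branch set, new eff) updates."""
        if self.likelihood_off:
            return 0.0, None
        V_new = st.V.copy()
        for domain, new_eff in changes:
            for b in domain:
                dw = self.lengths[b] * (math.exp(new_eff) - math.exp(st.eff[b]))
                if dw != 0.0:
                    s = self.tip_sets[b]
                    V_new[np.ix_(s, s)] += dw
        try:
            L = linalg.cholesky(V_new, lower=True)
        except linalg.LinAlgError:
            return -np.inf, None
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        Zx = linalg.solve_triangular(L, self.X, lower=True)
        zy = linalg.solve_triangular(L, self.y, lower=True)
        m = zy - Zx @ st.beta
        quad = float(m @ m)
        ll = self._ll(logdet, quad, st.log_s2)
        return ll - st.loglik, (V_new, L, logdet, Zx, zy, m, quad, ll)

    def _commit(self, st, domain, new_eff, cand) -> None:
        self._commit_multi(st, [(domain, new_eff)], cand)

    def _commit_multi(self, st, changes, cand) -> None:
        for domain, new_eff in changes:
            for b in domain:
                st.eff[b] = new_eff
        if cand is not None:
            st.V, st.L, st.logdet, st.Zx, st.zy, st.m, st.quad, st.loglik = cand

    def _move_rj(self, st, rng) -> None:
        """Toggle one branch's innovation indicator.

        Values are proposed from the innovation prior, so the acceptance
        ratio is the (tempered) likelihood ratio times the Bernoulli odds of
        the indicator flip.
        """
        b = int(rng.integers(self.B))
        p = self.priors.p_active
        if st.innov[b]:
            # remove the innovation: the domain re-inherits from above
            pb = self.parent_branch[b]
            new_eff = st.eff[pb] if pb >= 0 else 0.0
            dact = math.log1p(-p) - math.log(p)
            domain = self._domain(st, b)
            dll, cand = self._eff_change(st, domain, new_eff)
            if self._accept(rng, self.power * dll + dact):
                st.innov[b] = False
                st.val[b] = 0.0
                self._commit(st, domain, new_eff, cand)
        else:
            v = float(rng.normal(0.0, self.priors.log_r_scale))
            dact = math.log(p) - math.log1p(-p)
            domain = self._domain(st, b)
            dll, cand = self._eff_change(st, domain, v)
            if self._accept(rng, self.power * dll + dact):
                st.innov[b] = True
                st.val[b] = v
                self._commit(st, domain, v, cand)

    def _move_value(self, st, rng) -> None:
        """Random walk on one innovation's log-scalar (domain moves with it)."""
        inn = np.nonzero(st.innov)[0]
        if inn.size == 0:
            return
        b = int(inn[rng.integers(inn.size)])
        v_new = st.val[b] + float(rng.normal(0.0, self.proposals.log_r_step))
        dprior = self._log_prior_value(v_new) - self._log_prior_value(st.val[b])
        domain = self._domain(st, b)
        dll, cand = self._eff_change(st, domain, v_new)
        if self._accept(rng, self.power * dll + dprior):
            st.val[b] = v_new
            self._commit(st, domain, v_new, cand)

    def _propagate_eff(self, innov: np.ndarray, val: np.ndarray) -> np.ndarray:
        """Effective log-scalars implied by innovation indicators and values."""
        eff = np.empty(self.B)
        for b in range(self.B):  # branches are preorder: parents first
            if innov[b]:
                eff[b] = val[b]
            else:
                pb = self.parent_branch[b]
                eff[b] = eff[pb] if pb >= 0 else 0.0
        return eff

    def _eff_vector_change(self, st, eff_new: np.ndarray):
        """Candidate caches for an arbitrary new effective-scalar vector."""
        changed = np.nonzero(eff_new != st.eff)[0]
        changes = [([int(b)], float(eff_new[b])) for b in changed]
        return self._eff_change_multi(st, changes)

    def _neighbours(self, b: int) -> list[int]:
        out = [int(c) for c in self.child_branches[b]]
        if self.parent_branch[b] >= 0:
            out.append(int(self.parent_branch[b]))
        return out

    def _move_slide(self, st, rng) -> None:
        """Relocate one innovation to a neighbouring branch, value unchanged.

        Mixes over the anchor ambiguity that arises when a rate shift's stem
        cannot be distinguished from an adjacent branch. The Hastings ratio
        is the ratio of neighbourhood sizes; innovation count and value are
        unchanged so the prior terms cancel.
        """
        inn = np.nonzero(st.innov)[0]
        if inn.size == 0:
            return
        b = int(inn[rng.integers(inn.size)])
        nb = self._neighbours(b)
        if not nb:  # a tip branch attached directly to the root
            return
        t = nb[int(rng.integers(len(nb)))]
        if st.innov[t]:
            return
        innov_new = st.innov.copy()
        val_new = st.val.copy()
        innov_new[b] = False
        val_new[b] = 0.0
        innov_new[t] = True
        val_new[t] = st.val[b]
        eff_new = self._propagate_eff(innov_new, val_new)
        dll, cand = self._eff_vector_change(st, eff_new)
        hastings = math.log(len(nb)) - math.log(len(self._neighbours(t)))
        if self._accept(rng, self.power * dll + hastings):
            st.innov, st.val = innov_new, val_new
            if cand is not None:
                st.eff = eff_new
                st.V, st.L, st.logdet, st.Zx, st.zy, st.m, st.quad, st.loglik = cand
            else:
                st.eff = eff_new

    def _move_stem_isolation(self, st, rng) -> None:
        """Jointly innovate an internal branch and re-innovate its children.

        Forward (applicable when neither the branch nor any of its children
        innovates): the branch gets a fresh scalar from the prior while each
        child innovates at a value proposed near the branch's *old* effective
        scalar — isolating a rate change to a single internal branch, the
        configuration a clade-wide intercept (mean) shift induces. Reverse
        (branch and all children innovating): remove all these innovations.
        Mixed configurations are left untouched, which preserves detailed
        balance; child-value proposal densities enter the acceptance ratio.
        """
        b = int(self.internal_branches[rng.integers(self.internal_branches.size)])
        kids = self.child_branches[b]
        p = self.priors.p_active
        tau = self.proposals.stem_child_step
        log_odds = math.log(p) - math.log1p(-p)
        pb = self.parent_branch[b]
        eff_parent = float(st.eff[pb]) if pb >= 0 else 0.0
        if not st.innov[b] and not any(st.innov[c] for c in kids):
            old_eff = float(st.eff[b])  # == eff_parent by inheritance
            v_b = float(rng.normal(0.0, self.priors.log_r_scale))
            v_kids = [old_eff + float(rng.normal(0.0, tau)) for _ in kids]
            # prior(v_b) cancels against its proposal; child terms do not
            dq = sum(
                self._log_prior_value(v) - _normal_logpdf(v, old_eff, tau) for v in v_kids
            )
            changes = [([b], v_b)] + [
                (self._domain(st, int(c)), v) for c, v in zip(kids, v_kids)
            ]
            dll, cand = self._eff_change_multi(st, changes)
            if self._accept(rng, self.power * dll + (1 + len(kids)) * log_odds + dq):
                st.innov[b] = True
                st.val[b] = v_b
                for c, v in zip(kids, v_kids):
                    st.innov[c] = True
                    st.val[c] = v
                self._commit_multi(st, changes, cand)
        elif st.innov[b] and all(st.innov[c] for c in kids):
            # reverse: remove the stem + child innovations; the whole region
            # re-inherits from above
            dq = -sum(
                self._log_prior_value(float(st.val[c]))
                - _normal_logpdf(float(st.val[c]), eff_parent, tau)
                for c in kids
            )
            region = [b]
            for c in kids:
                region.extend(self._domain(st, int(c)))
            dll, cand = self._eff_change_multi(st, [(region, eff_parent)])
            if self._accept(rng, self.power * dll - (1 + len(kids)) * log_odds + dq):
                st.innov[b] = False
                st.val[b] = 0.0
                for c in kids:
                    st.innov[c] = False
                    st.val[c] = 0.0
                self._commit_multi(st, [(region, eff_parent)], cand)


@dataclass
class _State:
    beta: np.ndarray
    log_s2: float
    innov: np.ndarray  # innovation indicator per branch
    val: np.ndarray  # innovation values (log r), meaningful where innov
    eff: np.ndarray  # effective log r per branch (copied along the tree)
    # caches (absent in likelihood_off mode)
    V: np.ndarray | None = None
    L: np.ndarray | None = None
    logdet: float = 0.0
    Zx: np.ndarray | None = None
    zy: np.ndarray | None = None
    m: np.ndarray | None = None
    quad: float = 0.0
    loglik: float = 0.0

    def as_sample(self, iteration: int = -1) -> VRPosteriorSample:
        return VRPosteriorSample(
            beta=self.beta.copy(),
            sigma2=math.exp(self.log_s2),
            r=np.exp(self.eff),
            loglik=self.loglik,
            iteration=iteration,
        )


# ---------------------------------------------------------------------------
# driving loops


def _run(
    sampler: VariableRatesSampler, settings: ChainSettings, ess_warn: float = 500.0
) -> PosteriorTrace:
    rng = np.random.default_rng(settings.seed)
    st = sampler.init_state(rng)
    n_keep = (settings.iterations - settings.burn_in + settings.thin - 1) // settings.thin
    S, p, B = n_keep, sampler.p, sampler.B
    beta = np.empty((S, p))
    sigma2 = np.empty(S)
    r = np.empty((S, B))
    ll = np.empty(S)
    n_inn = np.empty(S)
    k = 0
    for it in range(settings.iterations):
        sampler.step(st, rng)
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            beta[k] = st.beta
            sigma2[k] = math.exp(st.log_s2)
            r[k] = np.exp(st.eff)
            ll[k] = st.loglik
            n_inn[k] = st.innov.sum()
            k += 1
    trace = PosteriorTrace(
        beta=beta[:k],
        sigma2=sigma2[:k],
        r=r[:k],
        loglik=ll[:k],
        coef_names=sampler.coef_names,
        tree=sampler.tree,
        settings=settings,
        n_innovations=n_inn[:k],
    )
    ess = {"sigma2_b": effective_sample_size(np.log(trace.sigma2))}
    for j, name in enumerate(sampler.coef_names):
        ess[name] = effective_sample_size(trace.beta[:, j])
    if sampler.variable_rates:
        ess["n_active"] = effective_sample_size(trace.n_active.astype(float))
    trace.ess = ess
    low = {k_: round(v, 1) for k_, v in ess.items() if v < ess_warn}
    if low:
        warnings.warn(f"effective sample sizes below {ess_warn:g}: {low}", stacklevel=3)
    return trace


def run_chain(
    spec: RegressionSpec,
    table: TraitTable,
    tree: Phylogeny,
    settings: ChainSettings | None = None,
    variable_rates: bool = True,
    ess_warn: float = 500.0,
) -> PosteriorTrace:
    """Run one MCMC chain of the variable-rates regression."""
    settings = settings or ChainSettings()
    df = table.reindex_to(tree.tip_labels)
    X, y = build_design(spec, df)
    sampler = VariableRatesSampler(
        X.to_numpy(float),
        y,
        tree,
        priors=settings.priors,
        proposals=settings.proposals,
        variable_rates=variable_rates,
        coef_names=list(X.columns),
    )
    return _run(sampler, settings, ess_warn)


def run_chains(
    spec: RegressionSpec,
    table: TraitTable,
    tree: Phylogeny,
    settings: ChainSettings | None = None,
    n_chains: int = 2,
    variable_rates: bool = True,
) -> list[PosteriorTrace]:
    """Independent replicate chains (seeds ``seed + i``)."""
    settings = settings or ChainSettings()
    return [
        run_chain(spec, table, tree, replace(settings, seed=settings.seed + i), variable_rates)
        for i in range(n_chains)
    ]


def mcmc_step(
    sampler: VariableRatesSampler, state: _State, rng: np.random.Generator
) -> _State:
    """Advance the chain by one elementary proposal (thin wrapper)."""
    return sampler.step(state, rng)


# ---------------------------------------------------------------------------
# posterior utilities


def vr_loglik(
    sample: VRPosteriorSample,
    spec: RegressionSpec,
    table: TraitTable,
    tree: Phylogeny,
) -> float:
    """Log-likelihood of one posterior sample (dense-matrix evaluation).

    The residual covariance is ``sigma_b^2 x V`` on the tree whose branch
    ``b`` has length ``l_b * r_b``.
    """
    df = table.reindex_to(tree.tip_labels)
    X, y = build_design(spec, df)
    X = np.column_stack([np.ones(len(y)), X.to_numpy(float)])
    if sample.beta.shape[0] != X.shape[1]:
        raise ValueError("sample beta dimension does not match the design")
    if sample.r.shape[0] != tree.n_branches:
        raise ValueError("sample r dimension does not match the tree")
    if np.any(sample.r < 0):
        raise ValueError("rate scalars must be >= 0")
    from .gls import phylo_covariance

    scaled = tree.scaled_by(sample.r)
    V = sample.sigma2 * phylo_covariance(scaled)
    resid = y - X @ sample.beta
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as exc:
        raise FloatingPointError("singular covariance: some tip has an all-zero path") from exc
    z = linalg.solve_triangular(L, resid, lower=True)
    n = len(y)
    return float(-0.5 * (n * LOG2PI + 2 * np.sum(np.log(np.diag(L))) + z @ z))


def compute_px(draws) -> float:
    """Proportion of a posterior on the minority side of zero.

    Zero draws count toward crossing; an all-zero posterior returns the
    degenerate 0.5 by convention. Px is in [0, 0.5].
    """
    x = np.asarray(draws, float)
    if x.size == 0:
        raise ValueError("compute_px needs at least one draw")
    pos = float(np.mean(x > 0))
    neg = float(np.mean(x < 0))
    zero = 1.0 - pos - neg
    return min(0.5, min(pos, neg) + zero)


def compute_px_diff(draws_a, draws_b) -> tuple[float, bool]:
    """Px of the per-iteration differences a - b; flags a credible difference.

    Returns ``(px_diff, different)`` with ``different = px_diff < 0.05``.
    """
    a = np.asarray(draws_a, float)
    b = np.asarray(draws_b, float)
    if a.shape != b.shape:
        raise ValueError("paired draws must have equal length")
    px = compute_px(a - b)
    return px, px < 0.05


def effective_sample_size(x: np.ndarray) -> float:
    """ESS by Geyer's initial monotone positive sequence estimator."""
    x = np.asarray(x, float)
    n = x.size
    if n < 4:
        return float(n)
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0:
        return float(n)
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    n_pairs = (n - 1) // 2
    gammas = []
    for m_ in range(n_pairs):
        g = rho[2 * m_] + rho[2 * m_ + 1]
        if g <= 0:
            break
        gammas.append(g)
    if not gammas:
        return float(n)
    for i in range(1, len(gammas)):  # initial monotone sequence
        gammas[i] = min(gammas[i], gammas[i - 1])
    tau = -1.0 + 2.0 * sum(gammas)
    tau = max(tau, 1.0 / n)
    return float(n / tau)


# ---------------------------------------------------------------------------
# sklearn-style front end


class VariableRatesRegression(BaseEstimator):
    """scikit-learn style front end to the variable-rates regression.

    Parameters mirror :class:`ChainSettings`; the tree is fixed at
    construction and ``fit(X, y)`` expects rows ordered like
    ``tree.tip_labels``. After fitting, ``trace_`` holds the posterior and
    ``coef_``/``sigma2_`` the posterior means.
    """

    def __init__(
        self,
        tree=None,
        iterations: int = 200_000,
        burn_in: int = 50_000,
        thin: int = 20,
        seed: int = 0,
        priors: VariableRatesPriors | None = None,
        proposals: ProposalSettings | None = None,
        variable_rates: bool = True,
    ):
        self.tree = tree
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.priors = priors
        self.proposals = proposals
        self.variable_rates = variable_rates

    def fit(self, X, y):
        names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        settings = ChainSettings(
            iterations=self.iterations,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.seed,
            priors=self.priors or VariableRatesPriors(),
            proposals=self.proposals or ProposalSettings(),
        )
        sampler = VariableRatesSampler(
            np.asarray(X, float),
            np.asarray(y, float),
            self.tree,
            priors=settings.priors,
            proposals=settings.proposals,
            variable_rates=self.variable_rates,
            coef_names=names,
        )
        self.trace_ = _run(sampler, settings)
        self.coef_names_ = self.trace_.coef_names
        self.coef_ = self.trace_.beta.mean(axis=0)
        self.sigma2_ = float(self.trace_.sigma2.mean())
        self.ess_ = self.trace_.ess
        return self

    def predict(self, X):
        X = np.column_stack([np.ones(np.asarray(X).shape[0]), np.asarray(X, float)])
        return X @ self.coef_
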