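# ratescape

Variable-rates phylogenetic regression for detecting bursts of trait
evolution — with Bayes-factor model comparison, heritable rate-shift
detection, and path-wise-rate trend analyses.

## The problem

Across vertebrates, testes mass varies enormously even after accounting for
body mass, and much of that variation tracks sperm competition: species in
mating systems with many competing males tend to carry larger testes
relative to their size. Two questions follow for comparative biologists:

1. **Where and when did relative testes mass evolve unusually fast?**
   Bursts of change concentrated on particular branches or clades of the
   phylogeny mark episodes of intense (probably sexual) selection.
2. **Have those bursts pushed in a consistent direction?** If rapid
   evolution in, say, socially monogamous lineages has mostly *shrunk*
   testes, species with the most accumulated rapid change should now have
   the smallest relative testes mass.

`ratescape` implements the full analysis chain for these questions on a
rooted time tree plus a species trait table, and ships a synthetic-data
generator with planted ground truth so every stage can be validated.

## The model

The core is a **variable-rates regression**: a phylogenetic GLS regression

&nbsp;&nbsp;&nbsp;&nbsp;*y = Xβ + ε*,&nbsp;&nbsp;&nbsp;
*ε* ~ MVN(0, σ<sub>b</sub>² · V(r))

where *y* is log₁₀ testes mass, *X* carries log₁₀ body mass (and, where
wanted, taxonomic class and interactions), σ<sub>b</sub>² is the background
Brownian-motion rate of residual evolution, and V(r) is the shared-path
covariance of the tree after each branch length (in time) is multiplied by
a non-negative scalar *r*. Branches with *r* > 1 evolved faster than
background; *r* < 1 slower. An MCMC with reversible-jump moves samples
which branches deviate, under a copy-or-innovate prior: each branch either
inherits its parent's effective scalar exactly or innovates a new one, so a
single innovation can propagate to a whole clade and branches with no
innovating ancestor sit at *r* = 1 exactly.

Downstream of the posterior:

* **Bayes factors** — stepping-stone marginal likelihoods compare the
  variable-rates model (m1) against a single-rate model (m0), on the scale
  BF = 2(log ml₁ − log ml₀); BF > 10 is conventionally "very strong".
* **Branch classification** — a branch is a rate increase iff *r* > 1 in
  more than 50% of posterior samples (σ<sub>v</sub>² = σ<sub>b</sub>²·r is
  its optimized rate).
* **Heritable rate shifts** — clades of ≥ 10 species whose stem branch
  differs in rate from its ancestor in > 50% of samples and whose
  descendant branches all inherit the new rate; 2–9-species clades are
  incipient shifts, single tips single-species shifts. Rate elevations
  confined to one internal branch are screened as **mean-shift candidates**
  (an intercept change in the clade's allometry) via a clade-dummy PGLS
  likelihood-ratio test on the time tree.
* **Path-wise rates & trends** — the sum of rate-scaled branch lengths from
  root to tip measures each species' accumulated rapid evolution; per
  taxonomic group, `log_testes ~ log_body + mating_system * pathrate` on
  the median rate-scaled tree (ML PGLS, Bonferroni-corrected) tests for
  directional trends, with an intercept-difference fall-back model when no
  slope is credible.

## Worked example

```python
from ratescape import (
    SimulationConfig, ShiftSpec, simulate_dataset, simulate_tree, find_clade,
    RegressionSpec, gls_fit, run_chain, ChainSettings,
    summarize_branch_rates, detect_heritable_shifts,
)

# a 100-tip tree with an 8x rate burst planted on a 10-species clade
tree = simulate_tree(SimulationConfig(n_tips=100, seed=1))
a, b = find_clade(tree, 10, 11, min_stem=0.05)
ds = simulate_dataset(SimulationConfig(
    n_tips=100, seed=1, shifts=(ShiftSpec(anchor=(a, b), multiplier=8.0),)))

fit = gls_fit(RegressionSpec(), ds.table, ds.tree)
print(f"allometric slope {fit.coef['log_body']:.3f}, r2 {fit.r2:.3f}")

trace = run_chain(RegressionSpec(), ds.table, ds.tree,
                  ChainSettings(iterations=100_000, burn_in=25_000, thin=20, seed=1))
shifts = detect_heritable_shifts(summarize_branch_rates(trace, ds.tree), trace, ds.tree)
for s in shifts:
    print(s.kind, s.size, s.direction, f"stem frac {s.stem_vs_ancestor_frac:.2f}")
```

Output:

```
allometric slope 0.717, r2 0.702
heritable 10 increase stem frac 0.95
```

The slope recovers the simulated allometry (true value 0.67), and the
planted 10-species burst is recovered as a heritable rate increase whose
stem branch exceeds its ancestor's rate in 95% of posterior samples.

The same pipeline runs from the shell:

```bash
ratescape run-all --config analysis.yaml --out results/
```

with subcommands `validate`, `simulate`, `vr-run`, `bf`, `shifts` and
`trends` for the individual stages.

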