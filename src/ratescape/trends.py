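"""Directional-trend analyses: does accumulated rapid evolution predict trait values?

For one taxonomic group at a time, the testes-body allometry is extended
with social mating system (MS), the median path-wise rate, and their
interaction, fitted by ML PGLS on the median rate-scaled tree:

    log testes ~ log body + MS + pathrate + MS x pathrate

A negative per-category path-wise-rate slope means that species which have
experienced the most rapid testes-mass evolution have ended up with the
smallest relative testes mass — a sustained directional trend. Categories
with fewer than ``min_n`` species (default 20, ten data points per
estimated parameter) are merged or excluded before fitting. P-values are
Bonferroni-adjusted across the mating-system categories fitted within the
group.

Where no category shows a credible slope, a fall-back intercept model

    log testes ~ log body + MS        (vs.  log testes ~ log body)

tests whether average relative testes mass differs among mating systems,
with a likelihood-ratio (D) statistic on ``levels - 1`` degrees of freedom
and pairwise intercept contrasts oriented so a positive value means the
column category has larger testes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gls import GlsFit, RegressionSpec, gls_fit, likelihood_ratio_test
from .rates import PathwiseRates
from .traits import TraitTable
from .tree import Phylogeny

__all__ = [
    "TrendsResult",
    "fit_trends_model",
    "fit_intercept_model",
    "bonferroni_adjust",
    "predict_trait",
]

logger = logging.getLogger(__name__)


@dataclass
class TrendsResult:
    """Results of the trends (slope) and/or intercept models for one group."""

    group: str
    model_branch: str  # 'slope' or 'intercept'
    n: int
    n_per_category: dict[str, int]
    categories: list[str]  # fitted after merging/exclusion
    reference: str
    #: per-category slope of trait on path-wise rate
    slopes: pd.DataFrame | None = None  # index category: estimate, se, p, p_adj
    interaction_D: float | None = None
    interaction_df: int | None = None
    interaction_p: float | None = None
    #: intercept model outputs
    intercept_D: float | None = None
    intercept_df: int | None = None
    intercept_p: float | None = None
    contrasts: pd.DataFrame | None = None  # pairwise intercept differences
    not_fitted: dict[str, str] = field(default_factory=dict)
    fit: GlsFit | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        if self.slopes is not None:
            for cat, row in self.slopes.iterrows():
                rows.append(
                    {
                        "group": self.group,
                        "category": cat,
                        "term": "pathrate_slope",
                        "estimate": row["estimate"],
                        "se": row["se"],
                        "p": row["p"],
                        "p_adj": row["p_adj"],
                        "model_branch": self.model_branch,
                    }
                )
        if self.contrasts is not None:
            for _, row in self.contrasts.iterrows():
                rows.append(
                    {
                        "group": self.group,
                        "category": f"{row['column']}-{row['row']}",
                        "term": "intercept_difference",
                        "estimate": row["estimate"],
                        "se": row["se"],
                        "p": row["p"],
                        "p_adj": np.nan,
                        "model_branch": self.model_branch,
                    }
                )
        for cat, why in self.not_fitted.items():
            rows.append(
                {
                    "group": self.group,
                    "category": cat,
                    "term": "not_fitted",
                    "estimate": np.nan,
                    "se": np.nan,
                    "p": np.nan,
                    "p_adj": np.nan,
                    "model_branch": why,
                }
            )
        return pd.DataFrame(rows)


def bonferroni_adjust(pvalues, m: int | None = None) -> list[float]:
    """Bonferroni correction: ``min(1, p * m)``, order preserved."""
    p = list(pvalues)
    for v in p:
        if not 0 <= v <= 1:
            raise ValueError(f"p-value {v} outside [0, 1]")
    m = m if m is not None else len(p)
    if m < len(p):
        raise ValueError("m must be at least the number of tests")
    return [min(1.0, v * m) for v in p]


def _prepare_group(
    table: TraitTable,
    group: str,
    min_n: int,
    merge: dict[str, str] | None,
) -> tuple[pd.DataFrame, list[str], dict[str, str]]:
    df = table.data[table.data["clade_class"] == group].copy()
    df = df[df["mating_system"].notna()]
    if merge:
        df["mating_system"] = df["mating_system"].map(lambda s: merge.get(s, s))
    counts = df["mating_system"].value_counts()
    not_fitted = {}
    keep = []
    for cat, n_cat in counts.items():
        if n_cat >= min_n:
            keep.append(cat)
        else:
            not_fitted[cat] = f"excluded: n={n_cat} < {min_n}"
            logger.info("group %s: category %s excluded (n=%d < %d)", group, cat, n_cat, min_n)
    df = df[df["mating_system"].isin(keep)]
    return df, sorted(keep), not_fitted


def _category_slopes(
    fit: GlsFit, categories: list[str], reference: str, n: int
) -> pd.DataFrame:
    """Per-category path-wise-rate slopes from the interaction fit."""
    names = fit.names
    idx = {name: i for i, name in enumerate(names)}
    base_i = idx["pathrate"]
    rows = {}
    dof = n - len(names)
    for cat in categories:
        if cat == reference:
            est = fit.coef.iloc[base_i]
            var = fit.vcov[base_i, base_i]
        else:
            inter = f"pathrate:mating_system[{cat}]"
            i2 = idx[inter]
            est = fit.coef.iloc[base_i] + fit.coef.iloc[i2]
            var = fit.vcov[base_i, base_i] + fit.vcov[i2, i2] + 2 * fit.vcov[base_i, i2]
        se = float(np.sqrt(var))
        t = est / se
        p = float(2 * stats.t.sf(abs(t), dof))
        rows[cat] = {"estimate": float(est), "se": se, "p": p}
    out = pd.DataFrame(rows).T
    out["p_adj"] = bonferroni_adjust(out["p"].tolist(), m=len(categories))
    return out


def fit_trends_model(
    table: TraitTable,
    scaled_tree: Phylogeny,
    pathrates: PathwiseRates | pd.Series,
    group: str,
    min_n: int = 20,
    merge: dict[str, str] | None = None,
    rate_summary: str = "median",
) -> TrendsResult:
    """Fit the trends (slope) model for one taxonomic group.

    ``scaled_tree`` is the median rate-scaled phylogeny; ``pathrates`` the
    path-wise rate summaries (or a ready per-tip Series). ``merge`` maps
    mating-system levels onto combined categories before the N >= 20 rule is
    applied (e.g. pooling monogamy and polygyny where either is too rare).
    Deterministic given its inputs.
    """
    rates = (
        pathrates.summary(rate_summary) if isinstance(pathrates, PathwiseRates) else pathrates
    )
    df, cats, not_fitted = _prepare_group(table, group, min_n, merge)
    if len(cats) == 0:
        raise ValueError(f"group {group!r} not analysable: all categories below n >= {min_n}")
    species = df["species"].tolist()
    sub = scaled_tree.prune_to(species)
    order = sub.tip_labels
    df = df.set_index("species").loc[order].reset_index()
    df["pathrate"] = rates.loc[order].to_numpy()

    counts = df["mating_system"].value_counts().to_dict()
    reference = "monogamy" if "monogamy" in cats else cats[0]

    if len(cats) == 1:
        # single category: a plain pathrate slope, no interaction test
        spec_full = RegressionSpec(
            response="log_testes", continuous=("log_body", "pathrate")
        )
        levels = tuple(sorted(set(table.ms_levels) | set(df["mating_system"].dropna())))
        sub_table = TraitTable(df, levels, table.class_levels)
        fit_full = gls_fit(spec_full, sub_table, sub)
        slopes = _category_slopes_single(fit_full, cats[0], len(df))
        return TrendsResult(
            group=group,
            model_branch="slope",
            n=len(df),
            n_per_category=counts,
            categories=cats,
            reference=reference,
            slopes=slopes,
            not_fitted=not_fitted,
            fit=fit_full,
        )

    spec_full = RegressionSpec(
        response="log_testes",
        continuous=("log_body", "pathrate"),
        categorical={"mating_system": reference},
        interactions=(("pathrate", "mating_system"),),
    )
    spec_nointer = RegressionSpec(
        response="log_testes",
        continuous=("log_body", "pathrate"),
        categorical={"mating_system": reference},
    )
    levels = tuple(sorted(set(table.ms_levels) | set(df["mating_system"].dropna())))
    sub_table = TraitTable(df, levels, table.class_levels)
    fit_full = gls_fit(spec_full, sub_table, sub)
    fit_nointer = gls_fit(spec_nointer, sub_table, sub)
    lrt = likelihood_ratio_test(fit_full, fit_nointer)

    slopes = _category_slopes(fit_full, cats, reference, len(df))
    return TrendsResult(
        group=group,
        model_branch="slope",
        n=len(df),
        n_per_category=counts,
        categories=cats,
        reference=reference,
        slopes=slopes,
        interaction_D=lrt.D,
        interaction_df=lrt.df,
        interaction_p=lrt.p,
        not_fitted=not_fitted,
        fit=fit_full,
    )


def _category_slopes_single(fit: GlsFit, category: str, n: int) -> pd.DataFrame:
    i = fit.names.index("pathrate")
    est = float(fit.coef.iloc[i])
    se = float(fit.se.iloc[i])
    p = float(2 * stats.t.sf(abs(est / se), n - len(fit.names)))
    return pd.DataFrame(
        {"estimate": [est], "se": [se], "p": [p], "p_adj": [p]}, index=[category]
    )


def fit_intercept_model(
    table: TraitTable,
    scaled_tree: Phylogeny,
    group: str,
    min_n: int = 20,
    merge: dict[str, str] | None = None,
) -> TrendsResult:
    """Intercept-difference fall-back: trait ~ body + MS on the scaled tree.

    Tests, by a likelihood-ratio (D) statistic against trait ~ body with
    ``levels - 1`` degrees of freedom, whether mating systems differ in
    average relative testes mass; reports pairwise contrasts with positive
    values meaning the column category is larger.
    """
    df, cats, not_fitted = _prepare_group(table, group, min_n, merge)
    if len(cats) < 2:
        raise ValueError(
            f"group {group!r}: need at least two mating-system categories, have {cats}"
        )
    species = df["species"].tolist()
    sub = scaled_tree.prune_to(species)
    order = sub.tip_labels
    df = df.set_index("species").loc[order].reset_index()
    counts = df["mating_system"].value_counts().to_dict()
    reference = "monogamy" if "monogamy" in cats else cats[0]

    levels = tuple(sorted(set(table.ms_levels) | set(df["mating_system"].dropna())))
    sub_table = TraitTable(df, levels, table.class_levels)
    spec_full = RegressionSpec(
        response="log_testes",
        continuous=("log_body",),
        categorical={"mating_system": reference},
    )
    spec_nested = RegressionSpec(response="log_testes", continuous=("log_body",))
    fit_full = gls_fit(spec_full, sub_table, sub)
    fit_nested = gls_fit(spec_nested, sub_table, sub)
    lrt = likelihood_ratio_test(fit_full, fit_nested)

    # pairwise contrasts: intercept(column) - intercept(row)
    names = fit_full.names
    idx = {c: names.index(f"mating_system[{c}]") for c in cats if c != reference}
    dof = len(df) - len(names)
    rows = []
    for i, row_cat in enumerate(cats):
        for col_cat in cats[i + 1 :]:
            if row_cat == reference:
                est = fit_full.coef.iloc[idx[col_cat]]
                var = fit_full.vcov[idx[col_cat], idx[col_cat]]
            elif col_cat == reference:
                est = -fit_full.coef.iloc[idx[row_cat]]
                var = fit_full.vcov[idx[row_cat], idx[row_cat]]
            else:
                i1, i2 = idx[col_cat], idx[row_cat]
                est = fit_full.coef.iloc[i1] - fit_full.coef.iloc[i2]
                var = fit_full.vcov[i1, i1] + fit_full.vcov[i2, i2] - 2 * fit_full.vcov[i1, i2]
            se = float(np.sqrt(var))
            p = float(2 * stats.t.sf(abs(est / se), dof))
            rows.append(
                {"row": row_cat, "column": col_cat, "estimate": float(est), "se": se, "p": p}
            )
    contrasts = pd.DataFrame(rows)
    return TrendsResult(
        group=group,
        model_branch="intercept",
        n=len(df),
        n_per_category=counts,
        categories=cats,
        reference=reference,
        intercept_D=lrt.D,
        intercept_df=lrt.df,
        intercept_p=lrt.p,
        contrasts=contrasts,
        not_fitted=not_fitted,
        fit=fit_full,
    )


def predict_trait(
    result: TrendsResult | GlsFit,
    body: float,
    category: str | None = None,
    pathrate: float | None = None,
) -> tuple[float, float]:
    """Predicted log10 testes mass (and grams) at the given covariates.

    Evaluates the fitted linear predictor at ``log_body = body`` for the
    requested mating-system category (and path-wise rate where the fit
    includes one). Returns ``(log10 grams, grams)``.
    """
    fit = result.fit if isinstance(result, TrendsResult) else result
    if fit is None:
        raise ValueError("result carries no fitted model")
    coef = fit.coef
    names = fit.names
    pred = float(coef.iloc[names.index("(intercept)")])
    pred += float(coef.iloc[names.index("log_body")]) * body
    if "pathrate" in names:
        if pathrate is None:
            raise ValueError("this fit requires a pathrate value")
        pred += float(coef.iloc[names.index("pathrate")]) * pathrate
    if category is not None:
        dummy = f"mating_system[{category}]"
        ref_cats = [n for n in names if n.startswith("mating_system[")]
        if dummy in names:
            pred += float(coef.iloc[names.index(dummy)])
            inter = f"pathrate:mating_system[{category}]"
            if inter in names:
                pred += float(coef.iloc[names.index(inter)]) * pathrate
        elif ref_cats and isinstance(result, TrendsResult) and category not in result.categories:
            raise ValueError(f"category {category!r} absent from the fit")
    return pred, 10.0**pred
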