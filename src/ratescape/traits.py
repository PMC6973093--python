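"""Species trait tables: response/predictor/category data aligned to tree tips.

The canonical table holds one row per species with log10 testes mass (the
response), log10 body mass (the allometric predictor), the major vertebrate
class, and — where known — the social mating system, a three-level proxy for
the level of sperm competition a species faces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import Phylogeny, normalize_label

__all__ = [
    "TraitTable",
    "read_trait_table",
    "match_and_prune",
    "CLASS_LEVELS",
    "MATING_SYSTEM_LEVELS",
]

CLASS_LEVELS = ("fish", "frogs", "birds", "mammals", "reptiles")
MATING_SYSTEM_LEVELS = ("monogamy", "polygyny", "polyandry")

#: canonical column names
COLUMNS = ("species", "log_testes", "log_body", "clade_class", "mating_system")


@dataclass
class TraitTable:
    """One row per species; masses on the log10-gram scale.

    ``data`` always carries the canonical columns: species, log_testes,
    log_body, clade_class, mating_system (the last may be missing / NaN).
    ``rejected`` records input rows dropped during reading (non-positive
    masses), for the rejection report.
    """

    data: pd.DataFrame
    ms_levels: tuple[str, ...] = MATING_SYSTEM_LEVELS
    class_levels: tuple[str, ...] = CLASS_LEVELS
    rejected: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        df = self.data.reset_index(drop=True).copy()
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trait table missing required columns: {missing}")
        df["species"] = df["species"].map(normalize_label)
        if df["species"].duplicated().any():
            dupes = sorted(df.loc[df["species"].duplicated(), "species"].unique())
            raise ValueError(f"duplicate species labels: {dupes}")
        for col in ("log_testes", "log_body"):
            vals = pd.to_numeric(df[col], errors="raise")
            if not np.all(np.isfinite(vals)):
                bad = df.loc[~np.isfinite(vals), "species"].tolist()
                raise ValueError(f"non-finite {col} for species {bad}")
            df[col] = vals.astype(float)
        bad_class = ~df["clade_class"].isin(self.class_levels)
        if bad_class.any():
            raise ValueError(
                "unknown taxonomic class tokens: "
                f"{sorted(df.loc[bad_class, 'clade_class'].unique())}"
            )
        known = df["mating_system"].isna() | df["mating_system"].isin(self.ms_levels)
        if not known.all():
            rows = df.index[~known].tolist()
            toks = sorted(df.loc[~known, "mating_system"].unique())
            raise ValueError(
                f"unknown mating-system tokens {toks} in rows {rows}; "
                f"allowed levels: {list(self.ms_levels)}"
            )
        self.data = df

    @property
    def species(self) -> list[str]:
        return self.data["species"].tolist()

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, species) -> "TraitTable":
        keep = set(species)
        df = self.data[self.data["species"].isin(keep)].reset_index(drop=True)
        return TraitTable(df, self.ms_levels, self.class_levels, self.rejected)

    def reindex_to(self, labels) -> pd.DataFrame:
        """The data frame reordered to match a tip-label ordering."""
        df = self.data.set_index("species")
        want = [normalize_label(l) for l in labels]
        missing = [l for l in want if l not in df.index]
        if missing:
            raise KeyError(f"species missing from trait table: {missing}")
        return df.loc[want].reset_index()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def read_trait_table(
    path,
    schema: dict[str, str] | None = None,
    *,
    masses_in_grams: bool = True,
    ms_levels: tuple[str, ...] = MATING_SYSTEM_LEVELS,
    class_levels: tuple[str, ...] = CLASS_LEVELS,
) -> TraitTable:
    """Read a CSV trait table.

    Parameters
    ----------
    schema : dict, optional
        Maps canonical names (species, testes_mass, body_mass, clade_class,
        mating_system) to the CSV's column headers, so alternative headers
        work. Defaults to the canonical names themselves.
    masses_in_grams : bool
        When True (default) the mass columns are raw grams and are
        log10-transformed here; rows with non-positive masses are rejected
        and reported in ``TraitTable.rejected``. When False the columns are
        taken to be log10 values already.
    """
    schema = schema or {}
    col = {
        "species": schema.get("species", "species"),
        "testes": schema.get("testes_mass", "testes_mass" if masses_in_grams else "log_testes"),
        "body": schema.get("body_mass", "body_mass" if masses_in_grams else "log_body"),
        "clade_class": schema.get("clade_class", "clade_class"),
        "mating_system": schema.get("mating_system", "mating_system"),
    }
    raw = pd.read_csv(path)
    missing = [c for c in col.values() if c != col["mating_system"] and c not in raw.columns]
    if missing:
        raise ValueError(f"trait CSV missing required columns: {missing}")
    has_ms = col["mating_system"] in raw.columns

    testes = pd.to_numeric(raw[col["testes"]], errors="coerce")
    body = pd.to_numeric(raw[col["body"]], errors="coerce")
    if masses_in_grams:
        ok = (testes > 0) & (body > 0)
        rejected = raw.loc[~ok].copy()
        rejected["reason"] = np.where(
            testes[~ok] <= 0, "non-positive testes mass", "non-positive body mass"
        )
        raw, testes, body = raw.loc[ok], testes[ok], body[ok]
        log_testes, log_body = np.log10(testes), np.log10(body)
    else:
        rejected = raw.iloc[0:0].copy()
        log_testes, log_body = testes, body

    df = pd.DataFrame(
        {
            "species": raw[col["species"]].astype(str),
            "log_testes": log_testes.to_numpy(float),
            "log_body": log_body.to_numpy(float),
            "clade_class": raw[col["clade_class"]].astype(str),
            "mating_system": raw[col["mating_system"]] if has_ms else pd.Series(
                [pd.NA] * len(raw), index=raw.index
            ),
        }
    )
    return TraitTable(df, ms_levels, class_levels, rejected=rejected)


def match_and_prune(tree: Phylogeny, table: TraitTable) -> tuple[Phylogeny, TraitTable]:
    """Restrict tree and table to their common species.

    Matching is exact after whitespace-to-underscore normalization and case
    folding (no fuzzy matching). Pruning preserves every retained tip's
    root-to-tip path length.
    """
    tree_norm = {normalize_label(l): l for l in tree.tip_labels}
    table_species = set(table.species)
    common_norm = sorted(set(tree_norm) & table_species)
    if not common_norm:
        raise ValueError("no species in common between tree and trait table")
    pruned = tree.prune_to([tree_norm[s] for s in common_norm])
    return pruned, table.subset(common_norm)
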