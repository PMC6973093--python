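"""End-to-end orchestration: validate -> simulate? -> vr-run -> bf? -> shifts -> trends.

A single YAML/JSON config drives the full analysis. Every run writes a
manifest recording the config hash, input digests, per-stage outputs and
seeds, so stochastic stages reproduce bit-for-bit from the same manifest;
stages whose inputs and config are unchanged are skipped on re-run when
their outputs are already present.

The global ``seed`` is expanded into fixed per-stage substreams (stable
offsets), so individual stages can be re-run independently yet
reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gls import RegressionSpec, gls_fit
from .marginal import SteppingStoneSettings, bayes_factor_analysis
from .rates import (
    detect_heritable_shifts,
    flag_mean_shift,
    median_scaled_tree,
    pathwise_rates,
    summarize_branch_rates,
)
from .simulate import ShiftSpec, SimulationConfig, TrendSpec, simulate_dataset
from .traits import TraitTable, match_and_prune, read_trait_table
from .tree import Phylogeny, read_newick, write_newick
from .trends import fit_intercept_model, fit_trends_model
from .vr import ChainSettings, run_chain

__all__ = ["RunManifest", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

# per-stage seed offsets (global seed + offset, kept below 2**31)
STAGE_SEEDS = {"simulate": 11, "vr": 23, "bf": 37, "trends": 51}


def _digest_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _digest_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    package_version: str
    inputs: dict[str, str] = field(default_factory=dict)
    stages: dict[str, dict] = field(default_factory=dict)
    created: str = ""

    def save(self, path: Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def _load_trace(trace_path, r_path, tree, settings):
    df = pd.read_csv(trace_path)
    r = pd.read_csv(r_path).to_numpy()
    from .vr import PosteriorTrace

    beta_cols = [c for c in df.columns if c not in ("sigma2_b", "loglik", "n_active")]
    return PosteriorTrace(
        beta=df[beta_cols].to_numpy(),
        sigma2=df["sigma2_b"].to_numpy(),
        r=r,
        loglik=df["loglik"].to_numpy(),
        coef_names=beta_cols,
        tree=tree,
        settings=settings,
        n_innovations=df["n_active"].to_numpy(),
    )


def load_config(source) -> dict:
    """Config from a YAML/JSON path or a ready dict."""
    if isinstance(source, dict):
        return source
    text = Path(source).read_text()
    return yaml.safe_load(text)


def _build_spec(model_cfg: dict | None) -> RegressionSpec:
    model_cfg = model_cfg or {}
    return RegressionSpec(
        response=model_cfg.get("response", "log_testes"),
        continuous=tuple(model_cfg.get("continuous", ["log_body"])),
        categorical=dict(model_cfg.get("categorical", {})),
        interactions=tuple(tuple(pair) for pair in model_cfg.get("interactions", [])),
    )


def _sim_config(cfg: dict, seed: int) -> SimulationConfig:
    shifts = tuple(
        ShiftSpec(
            anchor=tuple(s["anchor"]),
            multiplier=float(s.get("multiplier", 1.0)),
            kind=s.get("kind", "variance"),
            mean_offset=float(s.get("mean_offset", 0.0)),
        )
        for s in cfg.get("shifts", [])
    )
    trend = cfg.get("trend")
    kwargs = {
        k: cfg[k]
        for k in (
            "n_tips",
            "birth_rate",
            "death_rate",
            "intercepts",
            "slopes",
            "sigma2_b",
            "mating_frequencies",
            "mating_assignment",
            "body_mode",
            "body_mean",
            "sigma2_body",
            "tree_height",
        )
        if k in cfg
    }
    return SimulationConfig(
        seed=seed,
        shifts=shifts,
        trend=TrendSpec(**trend) if trend else None,
        **kwargs,
    )


def run_pipeline(config, out_dir=None) -> RunManifest:
    """Execute the configured stages in dependency order.

    Returns the manifest; raises on the first failing stage (the manifest,
    already written, records the failure point and downstream stages are not
    run).
    """
    cfg = load_config(config)
    out = Path(out_dir or cfg.get("out", "ratescape_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    config_hash = _digest_obj(cfg)

    manifest_path = out / "manifest.json"
    previous = None
    if manifest_path.exists():
        try:
            previous = RunManifest.load(manifest_path)
        except Exception:
            previous = None
    reusable = previous is not None and previous.config_hash == config_hash

    manifest = RunManifest(
        config_hash=config_hash,
        seed=seed,
        package_version=__version__,
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    def record(stage: str, outputs: dict[str, Path], extra: dict | None = None) -> None:
        manifest.stages[stage] = {
            "status": "ok",
            "outputs": {k: _digest_file(p) for k, p in outputs.items()},
            **(extra or {}),
        }
        manifest.save(manifest_path)

    def cached(stage: str, paths: list[Path]) -> bool:
        if not reusable or stage not in previous.stages:
            return False
        prev = previous.stages[stage]
        if prev.get("status") != "ok":
            return False
        return all(p.exists() for p in paths)

    def fail(stage: str, exc: Exception):
        manifest.stages[stage] = {"status": "failed", "error": str(exc)}
        manifest.save(manifest_path)
        raise

    # ---- stage: inputs (validate or simulate) -----------------------------
    tree_path = out / "tree.nwk"
    traits_path = out / "traits.csv"
    try:
        if cfg.get("simulate"):
            if not cached("simulate", [tree_path, traits_path]):
                sim_cfg = _sim_config(cfg["simulate"], seed + STAGE_SEEDS["simulate"])
                ds = simulate_dataset(sim_cfg)
                write_newick(ds.tree, tree_path)
                ds.table.data.to_csv(traits_path, index=False)
                write_newick(ds.scaled_tree, out / "true_scaled_tree.nwk")
                ds.pathwise_rates.to_csv(out / "true_pathwise_rates.csv")
            record("simulate", {"tree": tree_path, "traits": traits_path})
            tree = read_newick(tree_path)
            table = read_trait_table(traits_path, masses_in_grams=False)
        else:
            src_tree = Path(cfg["tree"])
            src_traits = Path(cfg["traits"])
            manifest.inputs = {
                str(src_tree): _digest_file(src_tree),
                str(src_traits): _digest_file(src_traits),
            }
            tree = read_newick(src_tree)
            table = read_trait_table(
                src_traits,
                schema=cfg.get("schema"),
                masses_in_grams=cfg.get("masses_in_grams", True),
            )
        tree, table = match_and_prune(tree, table)
        manifest.stages["validate"] = {
            "status": "ok",
            "n_species": len(table),
            "n_tips": tree.n_tips,
        }
        manifest.save(manifest_path)
    except Exception as exc:  # pragma: no cover - error path
        fail("validate", exc)

    spec = _build_spec(cfg.get("model"))

    # ---- stage: baseline GLS ---------------------------------------------
    gls_path = out / "gls_fit.json"
    try:
        fit = gls_fit(spec, table, tree)
        gls_path.write_text(
            json.dumps(
                {
                    "coef": fit.coef.to_dict(),
                    "se": fit.se.to_dict(),
                    "sigma2": fit.sigma2,
                    "loglik": fit.loglik,
                    "r2": fit.r2,
                    "n": fit.n,
                },
                indent=2,
            )
        )
        record("gls", {"fit": gls_path}, {"r2": fit.r2})
    except Exception as exc:  # pragma: no cover
        fail("gls", exc)

    # ---- stage: variable-rates MCMC --------------------------------------
    vr_cfg = cfg.get("vr", {})
    trace_path = out / "trace.csv"
    trace_meta = out / "trace_meta.json"
    r_path = out / "trace_r.csv"
    try:
        settings = ChainSettings(
            iterations=int(vr_cfg.get("iterations", 60_000)),
            burn_in=int(vr_cfg.get("burn_in", 15_000)),
            thin=int(vr_cfg.get("thin", 15)),
            seed=seed + STAGE_SEEDS["vr"],
        )
        if cached("vr", [trace_path, r_path, trace_meta]):
            trace = _load_trace(trace_path, r_path, tree, settings)
        else:
            trace = run_chain(
                spec, table, tree, settings, ess_warn=vr_cfg.get("ess_warn", 500)
            )
            trace.to_frame().to_csv(trace_path, index=False)
            pd.DataFrame(trace.r).to_csv(r_path, index=False)
            trace_meta.write_text(
                json.dumps(
                    {
                        "iterations": settings.iterations,
                        "burn_in": settings.burn_in,
                        "thin": settings.thin,
                        "seed": settings.seed,
                        "n_samples": len(trace),
                        "ess": trace.ess,
                        "branch_order": "column b of trace_r.csv is the branch above preorder node b+1",
                    },
                    indent=2,
                )
            )
        record("vr", {"trace": trace_path, "r": r_path, "meta": trace_meta}, {"ess": trace.ess})
    except Exception as exc:  # pragma: no cover
        fail("vr", exc)

    # ---- stage: Bayes factor ---------------------------------------------
    bf_cfg = cfg.get("bf", {})
    if bf_cfg.get("enabled", False):
        bf_path = out / "bayes_factor.json"
        try:
            ss = SteppingStoneSettings(
                K=int(bf_cfg.get("K", 20)),
                iterations=int(bf_cfg.get("iterations", 5_000)),
                burn_in=int(bf_cfg.get("burn_in", 1_250)),
                loglik_thin=int(bf_cfg.get("loglik_thin", 2)),
                seed=seed + STAGE_SEEDS["bf"],
            )
            report = bayes_factor_analysis(spec, table, tree, settings=ss)
            bf_path.write_text(json.dumps(report.to_dict(), indent=2))
            record("bf", {"report": bf_path}, {"bf": report.bf, "support": report.support})
        except Exception as exc:  # pragma: no cover
            fail("bf", exc)

    # ---- stage: shifts + scaled tree + path-wise rates --------------------
    shifts_cfg = cfg.get("shifts", {})
    shifts_path = out / "shifts.csv"
    scaled_path = out / "median_scaled_tree.nwk"
    pwr_path = out / "pathwise_rates.csv"
    summaries_path = out / "branch_rates.csv"
    try:
        summaries = summarize_branch_rates(trace, tree)
        pd.DataFrame(
            [
                {
                    "branch": s.branch,
                    "node": s.node,
                    "frac_gt1": s.frac_gt1,
                    "frac_lt1": s.frac_lt1,
                    "median_r": s.median_r,
                    "classification": s.classification,
                }
                for s in summaries
            ]
        ).to_csv(summaries_path, index=False)
        reports = detect_heritable_shifts(
            summaries,
            trace,
            tree,
            min_size=int(shifts_cfg.get("min_size", 10)),
            include_single_branch=True,
        )
        reports = [
            flag_mean_shift(s, table, tree, trace, spec)
            if not tree.is_tip(s.anchor_node)
            else s
            for s in reports
        ]
        pd.DataFrame(
            [
                {
                    "shift_id": s.shift_id,
                    "anchor_node": s.anchor_node,
                    "size": s.size,
                    "kind": s.kind,
                    "direction": s.direction,
                    "stem_frac": s.stem_vs_ancestor_frac,
                    "max_descendant_diff_frac": s.max_descendant_diff_frac,
                    "mean_shift_p": s.mean_shift_p,
                    "tips": ";".join(s.tips),
                }
                for s in reports
            ]
        ).to_csv(shifts_path, index=False)
        scaled = median_scaled_tree(trace, tree)
        write_newick(scaled, scaled_path)
        pwr = pathwise_rates(trace, tree)
        pd.DataFrame(
            {"median": pwr.median, "mean": pwr.mean, "mode": pwr.mode}
        ).to_csv(pwr_path, index_label="species")
        record(
            "shifts",
            {"shifts": shifts_path, "scaled_tree": scaled_path, "pathwise": pwr_path},
            {"n_shifts": len(reports)},
        )
    except Exception as exc:  # pragma: no cover
        fail("shifts", exc)

    # ---- stage: trends ----------------------------------------------------
    trends_cfg = cfg.get("trends", {})
    groups = trends_cfg.get("groups", [])
    if groups:
        trends_path = out / "trends.csv"
        try:
            frames = []
            for group in groups:
                merge = trends_cfg.get("merge", {}).get(group)
                res = fit_trends_model(
                    table,
                    scaled,
                    pwr,
                    group,
                    min_n=int(trends_cfg.get("min_n", 20)),
                    merge=merge,
                )
                frames.append(res.to_frame())
                significant = (
                    res.slopes is not None and (res.slopes["p_adj"] < 0.05).any()
                )
                if not significant and len(res.categories) >= 2:
                    res_i = fit_intercept_model(
                        table,
                        scaled,
                        group,
                        min_n=int(trends_cfg.get("min_n", 20)),
                        merge=merge,
                    )
                    frames.append(res_i.to_frame())
            pd.concat(frames, ignore_index=True).to_csv(trends_path, index=False)
            record("trends", {"trends": trends_path})
        except Exception as exc:  # pragma: no cover
            fail("trends", exc)

    return manifest
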