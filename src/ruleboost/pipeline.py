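"""End-to-end orchestration of the model-development pipeline.

One call runs the whole study design: load the raw cohort, drop constant
features, impute the full table once for feature selection, rank
predictors by chi-squared, mine (or load) the rule knowledge base, build
the hybrid predictor sets, evaluate base and hybrid models over repeated
random splits for every candidate k, select the operating k per model by
highest mean MCC, and write summaries, curves and a reproducibility
manifest to the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortTable,
    describe_cohort,
    drop_constant_features,
    fit_mode,
    impute,
    read_cohort,
    DEFAULT_MISSING_TOKENS,
)
from .evaluate import repeated_evaluation, sweep_predictor_counts
from .metrics import averaged_roc, paired_t_test
from .models import BoostConfig
from .rules import (
    DEFAULT_RANK_DELTAS,
    RuleKB,
    assign_ranks,
    mine_rules,
    select_kb,
)
from .selection import merge_with_kb_predictors, predictor_sweep

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MiningConfig:
    min_support: int = 10
    min_effect_ratio: float = 1.5
    max_arity: int = 3
    polarities: str = "both"
    max_rules: int = 20


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run depends on; serialized into the manifest."""

    cohort_path: str | None = None
    kb_path: str | None = None
    output_dir: str = "ruleboost_run"
    outcome_column: str = "events"
    missing_tokens: tuple[str, ...] = DEFAULT_MISSING_TOKENS
    fraction_test: float = 0.2
    n_iterations: int = 100
    boost: BoostConfig = field(default_factory=BoostConfig)
    mining: MiningConfig = field(default_factory=MiningConfig)
    rank_deltas: dict = field(default_factory=lambda: dict(DEFAULT_RANK_DELTAS))
    threshold: float = 0.5
    ece_bins: int = 10
    base_seed: int = 0
    k_values: tuple[int, ...] | None = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "boost" in raw and isinstance(raw["boost"], dict):
            raw["boost"] = BoostConfig(**raw["boost"])
        if "mining" in raw and isinstance(raw["mining"], dict):
            raw["mining"] = MiningConfig(**raw["mining"])
        if "missing_tokens" in raw:
            raw["missing_tokens"] = tuple(raw["missing_tokens"])
        if raw.get("k_values") is not None:
            raw["k_values"] = tuple(int(k) for k in raw["k_values"])
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["missing_tokens"] = list(self.missing_tokens)
        d["k_values"] = list(self.k_values) if self.k_values is not None else None
        return d


def _stage(name: str):
    logger.info("stage %s: starting", name)
    return time.perf_counter()


def _stage_done(name: str, t0: float, **info) -> None:
    extras = " ".join(f"{k}={v}" for k, v in info.items())
    logger.info("stage %s: done in %.2fs %s", name, time.perf_counter() - t0, extras)


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(cfg: RunConfig, cohort: CohortTable | None = None) -> Path:
    """Execute the full pipeline; returns the output directory.

    ``cohort`` may be passed directly (e.g. a synthetic table), otherwise
    it is read from ``cfg.cohort_path``.  Identical config and inputs give
    bit-identical summary output.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    t0 = _stage("load")
    if cohort is None:
        if cfg.cohort_path is None:
            raise ValueError("run_pipeline needs a cohort or cfg.cohort_path")
        cohort = read_cohort(cfg.cohort_path, cfg.outcome_column, cfg.missing_tokens)
    _stage_done("load", t0, rows=cohort.n_patients, features=len(cohort.feature_names))

    t0 = _stage("preprocess")
    trimmed, removed = drop_constant_features(cohort)
    full_imputed = impute(trimmed, fit_mode(trimmed))
    describe_cohort(full_imputed, cfg.outcome_column).to_csv(out / "describe.csv", index=False)
    _stage_done("preprocess", t0, removed=len(removed), candidates=len(trimmed.feature_names))

    t0 = _stage("select")
    sweep = predictor_sweep(full_imputed)
    sweep.to_json(out / "predictor_sweep.json")
    sweep.scores_frame().to_csv(out / "feature_scores.csv", index=False)
    _stage_done("select", t0, n_sets=len(sweep.sets))

    t0 = _stage("knowledge_base")
    if cfg.kb_path is not None:
        path = Path(cfg.kb_path)
        if path.suffix == ".csv":
            kb = RuleKB.from_csv(path, cfg.rank_deltas, cfg.mining.max_rules)
        else:
            kb = RuleKB.from_json(path)
    else:
        mined = mine_rules(
            full_imputed,
            min_support=cfg.mining.min_support,
            min_effect_ratio=cfg.mining.min_effect_ratio,
            max_arity=cfg.mining.max_arity,
            polarities=cfg.mining.polarities,
        )
        ranked = assign_ranks(mined) if mined else []
        kb = select_kb(ranked, cfg.mining.max_rules, cfg.rank_deltas)
    kb.to_json(out / "kb.json")
    kb.to_csv(out / "kb.csv")
    _stage_done("knowledge_base", t0, rules=len(kb.rules))

    t0 = _stage("hybrid_sets")
    hybrid_sweep = merge_with_kb_predictors(sweep, kb)
    hybrid_sweep.to_json(out / "hybrid_predictor_sweep.json")
    _stage_done("hybrid_sets", t0)

    t0 = _stage("sweep")
    result = sweep_predictor_counts(
        trimmed,
        sweep,
        hybrid_sweep=hybrid_sweep,
        kb=kb,
        cfg=cfg.boost,
        n_iter=cfg.n_iterations,
        base_seed=cfg.base_seed,
        fraction_test=cfg.fraction_test,
        threshold=cfg.threshold,
        ece_bins=cfg.ece_bins,
        k_values=cfg.k_values,
    )
    result.curve_frame().to_csv(out / "mcc_sweep.csv", index=False)
    _stage_done("sweep", t0, best_k=result.best_k)

    t0 = _stage("final_models")
    final = {}
    tests = {}
    roc_frames = []
    for model in ("base", "hybrid"):
        k_star = result.best_k[model]
        rerun = repeated_evaluation(
            trimmed,
            sweep.sets[k_star],
            kb=kb if model == "hybrid" else None,
            cfg=cfg.boost,
            n_iter=cfg.n_iterations,
            base_seed=cfg.base_seed,
            fraction_test=cfg.fraction_test,
            threshold=cfg.threshold,
            ece_bins=cfg.ece_bins,
        )
        summary = rerun.hybrid if model == "hybrid" else rerun.base
        summary.per_iteration.to_csv(out / f"metrics_{model}.csv", index=False)
        final[model] = {"k": k_star, "metrics": summary.summary()}
        roc = averaged_roc(rerun.roc_inputs(model))
        roc_frames.append(
            pd.DataFrame(
                {
                    "model": model,
                    "fpr": roc.fpr_grid,
                    "tpr_mean": roc.tpr_mean,
                    "tpr_sd": roc.tpr_sd,
                }
            )
        )
        final[model]["roc_area"] = roc.area()
        final[model]["summary_vectors"] = summary  # dropped before serialization
    pd.concat(roc_frames, ignore_index=True).to_csv(out / "roc_grid.csv", index=False)
    for metric in ("f1", "auc", "mcc", "ece"):
        res = paired_t_test(
            final["hybrid"]["summary_vectors"].per_iteration[metric],
            final["base"]["summary_vectors"].per_iteration[metric],
        )
        tests[metric] = {
            "t": res.t,
            "p": res.p,
            "mean_difference": res.mean_difference,
            "zero_variance": res.zero_variance,
        }
    for model in final:
        del final[model]["summary_vectors"]
    _stage_done("final_models", t0)

    t0 = _stage("report")
    summary_payload = {
        "n_patients": cohort.n_patients,
        "n_events": int(cohort.outcome.sum()),
        "prevalence_pct": round(100.0 * float(cohort.outcome.mean()), 4),
        "removed_constant_features": removed,
        "n_candidate_predictors": len(trimmed.feature_names),
        "n_kb_rules": len(kb.rules),
        "models": final,
        "paired_tests_hybrid_vs_base": tests,
    }
    _json_dump(summary_payload, out / "summary.json")
    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "cohort_hash": cohort.content_hash(),
        "kb_features": kb.feature_names(),
        "base_seed": cfg.base_seed,
    }
    _json_dump(manifest, out / "manifest.json")
    _stage_done("report", t0)
    return out
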