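"""Repeated random-split evaluation harness and predictor-count sweep.

The study design this harness implements: split the raw cohort 80/20 at
random, fit per-feature modes on the training part only, impute both
parts, train the boosted model on the training rows, score the test rows,
and repeat 100 times with fresh splits.  Base and hybrid (rule-adjusted)
predictions are computed on identical splits, so per-iteration metrics are
paired and a paired t-test applies.  Running the harness for every top-k
predictor set and taking the k with the highest mean MCC selects the
operating model.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable, fit_mode, impute, split_cohort
from .metrics import ConfusionCounts, auc, ece, f1, mcc
from .models import BoostConfig, train_base, predict_base, classify
from .rules import RuleKB, apply_rules_frame
from .selection import PredictorSweep

METRIC_NAMES = ("f1", "auc", "mcc", "ece")


def iteration_seed(base_seed: int, iteration: int) -> int:
    """Deterministic per-iteration split seed.

    Derived by spawning ``numpy.random.SeedSequence([base_seed, iteration])``
    and truncating its first state word below 2**31, so iterations are
    independent streams yet fully reproducible from the base seed.
    """
    ss = np.random.SeedSequence([int(base_seed), int(iteration)])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass(frozen=True)
class MetricSummary:
    """Per-iteration F1/AUC/MCC/ECE vectors with their mean and SD."""

    per_iteration: pd.DataFrame  # columns: iteration, seed, split_hash, f1, auc, mcc, ece

    @property
    def n_iterations(self) -> int:
        return len(self.per_iteration)

    def mean(self) -> dict[str, float]:
        return {m: float(self.per_iteration[m].mean()) for m in METRIC_NAMES}

    def sd(self) -> dict[str, float]:
        ddof = 1 if self.n_iterations > 1 else 0
        return {m: float(self.per_iteration[m].std(ddof=ddof)) for m in METRIC_NAMES}

    def summary(self) -> dict[str, dict[str, float]]:
        means, sds = self.mean(), self.sd()
        return {m: {"mean": means[m], "sd": sds[m]} for m in METRIC_NAMES}


@dataclass(frozen=True)
class IterationScores:
    """Test-set scores of one split, kept for ROC averaging and audits."""

    seed: int
    split_hash: str
    labels: np.ndarray
    p_base: np.ndarray
    p_hybrid: np.ndarray | None


@dataclass(frozen=True)
class RepeatedEvaluation:
    """Paired base/hybrid metrics over repeated random splits."""

    base: MetricSummary
    hybrid: MetricSummary | None
    scores: list[IterationScores]

    def roc_inputs(self, model: str = "base"):
        for s in self.scores:
            probs = s.p_base if model == "base" else s.p_hybrid
            yield probs, s.labels


def _split_hash(test_index) -> str:
    text = ",".join(map(str, test_index))
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _metric_row(labels, probs, threshold, ece_bins):
    counts = ConfusionCounts.from_predictions(labels, classify(probs, threshold))
    return {
        "f1": f1(counts),
        "auc": auc(probs, labels),
        "mcc": mcc(counts),
        "ece": ece(probs, labels, n_bins=ece_bins).ece,
    }


def repeated_evaluation(
    t: CohortTable,
    predictors,
    kb: RuleKB | None = None,
    cfg: BoostConfig = BoostConfig(),
    n_iter: int = 100,
    base_seed: int = 0,
    fraction_test: float = 0.2,
    threshold: float = 0.5,
    ece_bins: int = 10,
    select_k: int | None = None,
) -> RepeatedEvaluation:
    """Evaluate base (and, given a KB, hybrid) models over repeated splits.

    Each iteration draws its own 80/20 split from a seed derived from
    ``base_seed``, refits modes on the training part, imputes both parts,
    trains the boosted model on the selected predictors, and scores the
    test rows.  Hybrid predictions reuse the same trained model and split,
    adjusted by the fired rules, so base and hybrid metrics are paired.

    By default the fixed ``predictors`` list (normally chosen on the full
    imputed table, as the study design prescribes) is used for every
    iteration.  Passing ``select_k`` switches to the nested, leakage-free
    alternative: predictors are re-ranked by chi-squared on each imputed
    training part and that iteration uses its own top ``select_k``.
    """
    predictors = list(predictors)
    if not predictors and select_k is None:
        raise ValueError("empty predictor set")
    base_rows, hybrid_rows, scores = [], [], []
    for i in range(n_iter):
        seed = iteration_seed(base_seed, i)
        pair = split_cohort(t, fraction_test=fraction_test, seed=seed)
        modes = fit_mode(pair.train)
        train = impute(pair.train, modes)
        test = impute(pair.test, modes)
        if select_k is not None:
            from .selection import rank_features

            ranking = rank_features(train)
            iter_predictors = [s.feature_name for s in ranking[:select_k]]
        else:
            iter_predictors = predictors
        model = train_base(train, iter_predictors, _iteration_cfg(cfg, seed))
        y_test = test.outcome.to_numpy()
        p_base = predict_base(model, test.features)
        split_hash = _split_hash(pair.test.features.index)
        meta = {"iteration": i, "seed": seed, "split_hash": split_hash}
        base_rows.append(meta | _metric_row(y_test, p_base, threshold, ece_bins))
        p_hybrid = None
        if kb is not None:
            p_hybrid = apply_rules_frame(kb, test.features, p_base)
            hybrid_rows.append(meta | _metric_row(y_test, p_hybrid, threshold, ece_bins))
        scores.append(IterationScores(seed, split_hash, y_test, p_base, p_hybrid))
    base_summary = MetricSummary(pd.DataFrame(base_rows))
    hybrid_summary = MetricSummary(pd.DataFrame(hybrid_rows)) if kb is not None else None
    return RepeatedEvaluation(base_summary, hybrid_summary, scores)


def _iteration_cfg(cfg: BoostConfig, split_seed: int) -> BoostConfig:
    # training seed tied to the split seed keeps the whole harness
    # reproducible from base_seed alone
    return BoostConfig(
        positive_class_weight=cfg.positive_class_weight,
        n_trees=cfg.n_trees,
        max_tree_depth=cfg.max_tree_depth,
        seed=(split_seed * 2 + 1) % 2**31,
    )


@dataclass(frozen=True)
class SweepResult:
    """Per-k base and hybrid metric summaries plus the MCC-argmax choice."""

    per_k: dict[int, dict[str, MetricSummary]]  # k -> {"base": ..., "hybrid": ...}
    best_k: dict[str, int]  # model -> selected k (argmax mean MCC, ties -> smaller k)

    def curve_frame(self) -> pd.DataFrame:
        """Long-format table of mean and SD MCC per k per model."""
        rows = []
        for k in sorted(self.per_k):
            for model, summary in self.per_k[k].items():
                rows.append(
                    {
                        "k": k,
                        "model": model,
                        "mcc_mean": summary.mean()["mcc"],
                        "mcc_sd": summary.sd()["mcc"],
                    }
                )
        return pd.DataFrame(rows)


def sweep_predictor_counts(
    t: CohortTable,
    sweep: PredictorSweep,
    hybrid_sweep: PredictorSweep | None = None,
    kb: RuleKB | None = None,
    cfg: BoostConfig = BoostConfig(),
    n_iter: int = 100,
    base_seed: int = 0,
    fraction_test: float = 0.2,
    threshold: float = 0.5,
    ece_bins: int = 10,
    k_values=None,
) -> SweepResult:
    """Run the repeated-split harness for every top-k predictor set.

    The hybrid model reuses the base model trained on each model set_k (it
    needs no extra training), so one fit per (k, iteration) serves both
    curves.  ``k_values`` restricts the sweep to a subset of k for quick
    runs; the selected k per model is the argmax of mean MCC, resolving
    ties toward the smaller (more parsimonious) k.
    """
    ks = sorted(k_values) if k_values is not None else sorted(sweep.sets)
    unknown = [k for k in ks if k not in sweep.sets]
    if unknown:
        raise ValueError(f"k values outside the sweep: {unknown}")
    if hybrid_sweep is not None and kb is not None:
        # the hybrid reuses the base fit, so its set_k must be the model
        # set_k plus the KB features and nothing else
        kb_features = set(kb.feature_names())
        for k in ks:
            expected = set(sweep.sets[k]) | kb_features
            if set(hybrid_sweep.sets[k]) != expected:
                raise ValueError(f"hybrid set for k={k} is not model set + KB features")
    per_k: dict[int, dict[str, MetricSummary]] = {}
    for k in ks:
        result = repeated_evaluation(
            t,
            sweep.sets[k],
            kb=kb,
            cfg=cfg,
            n_iter=n_iter,
            base_seed=base_seed,
            fraction_test=fraction_test,
            threshold=threshold,
            ece_bins=ece_bins,
        )
        per_k[k] = {"base": result.base}
        if result.hybrid is not None:
            per_k[k]["hybrid"] = result.hybrid
    best_k = {}
    for model in per_k[ks[0]]:
        means = [(per_k[k][model].mean()["mcc"], k) for k in ks]
        best = max(means, key=lambda pair: (pair[0], -pair[1]))
        best_k[model] = best[1]
    return SweepResult(per_k, best_k)
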