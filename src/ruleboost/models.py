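"""Gradient-boosted base classifier and the rule-adjusted hybrid predictor.

The base learner is an XGBoost binary classifier run with the three
hyperparameters that matter most on a small, imbalanced binary cohort:
``scale_pos_weight`` (class balance), ``n_estimators`` (kept very low to
avoid overfitting a few hundred rows) and ``max_depth``.  The hybrid
predictor needs no additional training: it post-adjusts the base model's
probability with the fired knowledge-base rules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

from .cohort import CohortTable, CohortError
from .rules import RuleKB, apply_rules_frame


@dataclass(frozen=True)
class BoostConfig:
    """Booster hyperparameters; defaults target a small imbalanced cohort.

    ``positive_class_weight`` multiplies the loss of positive (event) rows,
    compensating the ~5:1 class imbalance; 7 shallow-ish trees are enough
    for tens of binary predictors on a few hundred rows.
    """

    positive_class_weight: float = 5.2
    n_trees: int = 7
    max_tree_depth: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.positive_class_weight <= 0 or self.n_trees <= 0 or self.max_tree_depth <= 0:
            raise ValueError(f"BoostConfig values must be positive: {self}")

    def make_estimator(self) -> XGBClassifier:
        return XGBClassifier(
            n_estimators=self.n_trees,
            max_depth=self.max_tree_depth,
            scale_pos_weight=self.positive_class_weight,
            random_state=int(self.seed) % 2**31,
            n_jobs=1,
            objective="binary:logistic",
            eval_metric="logloss",
        )


@dataclass(frozen=True)
class FittedModel:
    """A trained boosted ensemble bound to the predictor list it was fed."""

    estimator: XGBClassifier
    predictors: tuple[str, ...]
    config: BoostConfig

    def resolved_params(self) -> dict:
        """Full resolved booster parameter set, for run manifests."""
        params = {k: v for k, v in self.estimator.get_params().items() if v is not None}
        params["predictors"] = list(self.predictors)
        return params


@dataclass(frozen=True)
class HybridModel:
    """Base model plus knowledge base; predicts rule-adjusted probabilities."""

    base: FittedModel
    kb: RuleKB

    def __post_init__(self):
        missing = set(self.kb.feature_names()) - set(self.base.predictors)
        if missing:
            raise CohortError(
                f"KB features absent from the hybrid predictor set: {sorted(missing)}"
            )


def train_base(train: CohortTable, predictors, cfg: BoostConfig) -> FittedModel:
    """Fit the boosted classifier on an imputed training cohort."""
    predictors = tuple(predictors)
    if not predictors:
        raise CohortError("empty predictor set")
    if train.n_missing:
        raise CohortError("training cohort must be imputed first")
    y = train.outcome.to_numpy()
    if len(np.unique(y)) < 2:
        raise CohortError("training set contains a single outcome class")
    X = train.subset_features(predictors).features.to_numpy(dtype=float)
    est = cfg.make_estimator()
    est.fit(X, y)
    return FittedModel(est, predictors, cfg)


def _predictor_matrix(m: FittedModel, rows: pd.DataFrame) -> np.ndarray:
    missing = [p for p in m.predictors if p not in rows.columns]
    if missing:
        raise CohortError(f"rows lack predictor columns: {missing}")
    if rows[list(m.predictors)].isna().to_numpy().any():
        raise CohortError("prediction rows contain missing values; impute first")
    return rows[list(m.predictors)].to_numpy(dtype=float)


def predict_base(m: FittedModel, rows: pd.DataFrame) -> np.ndarray:
    """Event probability for each row, in [0, 1]."""
    if len(rows) == 0:
        return np.empty(0)
    return m.estimator.predict_proba(_predictor_matrix(m, rows))[:, 1]


def predict_hybrid(h: HybridModel, rows: pd.DataFrame) -> np.ndarray:
    """Base probability post-adjusted by the fired knowledge-base rules."""
    if len(rows) == 0:
        return np.empty(0)
    p_base = predict_base(h.base, rows)
    if not h.kb.rules:
        return p_base
    return apply_rules_frame(h.kb, rows, p_base)


def classify(probabilities, threshold: float = 0.5) -> np.ndarray:
    """Binary prediction: 1 where probability >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0,1), got {threshold}")
    return (np.asarray(probabilities, dtype=float) >= threshold).astype(int)


def save_model(m: FittedModel, path) -> None:
    """Persist a fitted model as self-describing JSON (booster + metadata)."""
    payload = {
        "predictors": list(m.predictors),
        "config": asdict(m.config),
        "booster": m.estimator.get_booster().save_raw("json").decode(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> FittedModel:
    with open(path) as fh:
        payload = json.load(fh)
    cfg = BoostConfig(**payload["config"])
    est = cfg.make_estimator()
    est.load_model(bytearray(payload["booster"].encode()))
    return FittedModel(est, tuple(payload["predictors"]), cfg)
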