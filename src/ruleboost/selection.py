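"""Chi-squared predictor ranking and nested best-k predictor sets.

Every candidate predictor is scored against the outcome with the Pearson
chi-squared statistic on its 2x2 contingency table (no continuity
correction, as is conventional for feature selection).  Ranking the
statistic yields, for every k, the top-k predictor set; the sets are nested
by construction.  A hybrid sweep augments each set with the features used
by a rule knowledge base.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable, CohortError


@dataclass(frozen=True)
class FeatureScore:
    """Chi-squared association of one binary feature with the outcome."""

    feature_name: str
    chi2: float
    contingency: np.ndarray  # 2x2, rows = feature 0/1, cols = outcome 0/1

    def __post_init__(self):
        c = np.asarray(self.contingency)
        if c.shape != (2, 2) or (c < 0).any():
            raise ValueError("contingency must be a nonnegative 2x2 table")


@dataclass(frozen=True)
class PredictorSweep:
    """Ordered predictor ranking plus the nested top-k set for every k."""

    ranking: list[FeatureScore]
    sets: dict[int, list[str]]

    @property
    def max_k(self) -> int:
        return max(self.sets)

    def to_json(self, path) -> None:
        payload = {
            "ranking": [
                {"feature": s.feature_name, "chi2": s.chi2,
                 "contingency": np.asarray(s.contingency).astype(int).tolist()}
                for s in self.ranking
            ],
            "sets": {str(k): v for k, v in sorted(self.sets.items())},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.feature_name, s.chi2) for s in self.ranking],
            columns=["feature", "chi2"],
        )


def pearson_chi2_2x2(table: np.ndarray) -> float:
    """Closed-form Pearson statistic n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)).

    Returns 0 when any marginal is zero: a feature constant within the data
    (or a one-class outcome) carries no association and should rank last.
    """
    a, b = float(table[0, 0]), float(table[0, 1])
    c, d = float(table[1, 0]), float(table[1, 1])
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0.0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def chi2_score(feature, outcome) -> FeatureScore:
    """Score one binary feature against the binary outcome.

    Both vectors must be complete (impute first) and equally long.
    """
    f = np.asarray(feature, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if f.shape != y.shape:
        raise CohortError(f"length mismatch: {f.shape} vs {y.shape}")
    name = getattr(feature, "name", "") or ""
    table = np.empty((2, 2), dtype=np.int64)
    for fv in (0, 1):
        for yv in (0, 1):
            table[fv, yv] = int(np.sum((f == fv) & (y == yv)))
    return FeatureScore(str(name), pearson_chi2_2x2(table), table)


def rank_features(t: CohortTable) -> list[FeatureScore]:
    """All features scored and sorted by descending chi-squared.

    Ties break by ascending feature name so the ranking is deterministic.
    """
    if t.n_missing:
        raise CohortError("rank_features requires an imputed cohort")
    y = t.outcome.to_numpy()
    scores = [chi2_score(t.features[name], y) for name in t.features.columns]
    return sorted(scores, key=lambda s: (-s.chi2, s.feature_name))


def predictor_sweep(t: CohortTable) -> PredictorSweep:
    """Nested top-k predictor sets for k = 1..P from the chi-squared ranking."""
    ranking = rank_features(t)
    names = [s.feature_name for s in ranking]
    sets = {k: names[:k] for k in range(1, len(names) + 1)}
    return PredictorSweep(ranking, sets)


def merge_with_kb_predictors(sweep: PredictorSweep, kb) -> PredictorSweep:
    """Hybrid sweep: each set_k unioned with the features any KB rule uses.

    KB-only features append after the model set in alphabetical order, so
    hybrid sets stay deterministic and remain nested.
    """
    kb_features = sorted(kb.feature_names())
    known = {s.feature_name for s in sweep.ranking}
    unknown = [f for f in kb_features if f not in known]
    if unknown:
        raise CohortError(f"KB references unknown features: {unknown}")
    merged = {}
    for k, names in sweep.sets.items():
        extra = [f for f in kb_features if f not in names]
        merged[k] = list(names) + extra
    return PredictorSweep(sweep.ranking, merged)
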