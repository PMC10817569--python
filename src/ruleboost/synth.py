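"""Synthetic binary cohorts with planted conjunctive effects.

The generator emulates the statistical shape of a small emergency-
department cohort: a few hundred patients, a few dozen sparse binary
features, an imbalanced binary outcome (~17% events), a sprinkle of
missing values, and a handful of all-zero constant columns.  Outcome
probabilities follow a logistic model whose linear predictor is an
intercept plus the effects of whichever planted conjunctive antecedents a
patient satisfies; the intercept is calibrated by bisection on the
realized feature matrix so the expected prevalence hits its target.
Ground truth (planted rules, true probabilities) is returned alongside the
cohort so rule-recovery and ranking tests can score themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import CohortTable
from .rules import Literal, Rule, antecedent_key


@dataclass(frozen=True)
class PlantedRule:
    """A ground-truth conjunctive effect: literals plus a log-odds shift."""

    literals: tuple[Literal, ...]
    effect: float  # log-odds added when all literals are satisfied

    @property
    def key(self) -> str:
        return antecedent_key(self.literals)

    @property
    def direction(self) -> str:
        return "increase" if self.effect > 0 else "decrease"


@dataclass(frozen=True)
class SynthConfig:
    """Recipe for one synthetic cohort.

    Defaults mirror the kind of cohort the pipeline targets: 266 patients,
    35 informative-capable sparse features plus 3 constant columns (38
    feature columns and the outcome), ~17% prevalence, 2% missing cells.
    ``feature_sparsity`` may be a scalar or a per-feature sequence; by
    default rates span 0.02-0.5 geometrically, giving many rare features
    and a few common ones.
    """

    n_patients: int = 266
    n_features: int = 35
    feature_sparsity: object = None  # scalar, sequence, or None for the default span
    baseline_event_rate: float = 0.17
    planted_rules: tuple[PlantedRule, ...] = ()
    missing_rate: float = 0.02
    n_constant_features: int = 3
    seed: int = 0
    correlation_blocks: tuple[tuple[int, ...], ...] = ()  # latent-block stress mode
    block_flip: float = 0.1

    def sparsity_vector(self) -> np.ndarray:
        if self.feature_sparsity is None:
            rates = np.geomspace(0.02, 0.5, self.n_features)
        else:
            rates = np.broadcast_to(
                np.asarray(self.feature_sparsity, dtype=float), (self.n_features,)
            ).copy()
        if ((rates < 0) | (rates > 1)).any():
            raise ValueError("feature sparsity rates must lie in [0, 1]")
        return rates

    def validate(self) -> None:
        if not 0.0 < self.baseline_event_rate < 1.0:
            raise ValueError(
                f"baseline_event_rate must lie in (0,1), got {self.baseline_event_rate}"
            )
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must lie in [0,1), got {self.missing_rate}")
        names = set(feature_names(self.n_features))
        for rule in self.planted_rules:
            for lit in rule.literals:
                if lit.feature_name not in names:
                    raise ValueError(f"planted rule uses unknown feature {lit.feature_name!r}")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted, for recovery scoring."""

    planted_rules: tuple[PlantedRule, ...]
    true_probability: np.ndarray
    intercept: float


def feature_names(n: int, prefix: str = "f") -> list[str]:
    width = max(2, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Bisection for the intercept making mean(expit(b + eta)) hit target.

    Monotone in b, so plain bisection on a wide bracket converges to well
    below the 0.01 tolerance the generator promises.
    """
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if float(expit(mid + eta).mean()) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate(cfg: SynthConfig) -> tuple[CohortTable, GroundTruth]:
    """Draw one cohort and its ground truth, deterministically from the seed."""
    cfg.validate()
    rng = np.random.default_rng(int(cfg.seed) % 2**31)
    names = feature_names(cfg.n_features)
    rates = cfg.sparsity_vector()
    X = (rng.random((cfg.n_patients, cfg.n_features)) < rates).astype(float)
    for block in cfg.correlation_blocks:
        latent = (rng.random(cfg.n_patients) < float(np.mean(rates[list(block)]))).astype(float)
        for j in block:
            flip = rng.random(cfg.n_patients) < cfg.block_flip
            X[:, j] = np.where(flip, 1.0 - latent, latent)

    eta = np.zeros(cfg.n_patients)
    index = {name: j for j, name in enumerate(names)}
    for rule in cfg.planted_rules:
        mask = np.ones(cfg.n_patients, dtype=bool)
        for lit in rule.literals:
            mask &= X[:, index[lit.feature_name]] == lit.polarity
        eta += mask * rule.effect
    intercept = _calibrate_intercept(eta, cfg.baseline_event_rate)
    p_true = expit(intercept + eta)
    outcome = (rng.random(cfg.n_patients) < p_true).astype(int)

    if cfg.missing_rate > 0:
        missing = rng.random(X.shape) < cfg.missing_rate
        X = np.where(missing, np.nan, X)

    frame = pd.DataFrame(X, columns=names)
    for name in feature_names(cfg.n_constant_features, prefix="const"):
        frame[name] = 0.0
    ids = pd.RangeIndex(cfg.n_patients, name="patient")
    frame.index = ids
    cohort = CohortTable(frame, pd.Series(outcome, index=ids, name="events"))
    return cohort, GroundTruth(tuple(cfg.planted_rules), p_true, intercept)


@dataclass(frozen=True)
class RecoveryReport:
    """Precision/recall of planted-rule recovery by the miner."""

    n_planted: int
    n_mined: int
    n_recovered: int
    recall: float
    precision: float | None  # None when nothing was mined

    @property
    def precision_defined(self) -> bool:
        return self.precision is not None


def recovery_report(mined: list[Rule], truth: GroundTruth) -> RecoveryReport:
    """Score mined rules against the planted ground truth.

    A planted rule counts as recovered when its exact literal set appears
    among the mined rules with the matching direction.
    """
    mined_keys = {(r.key, r.direction) for r in mined}
    recovered = sum(
        1 for p in truth.planted_rules if (p.key, p.direction) in mined_keys
    )
    n_planted = len(truth.planted_rules)
    recall = recovered / n_planted if n_planted else 1.0
    planted_keys = {(p.key, p.direction) for p in truth.planted_rules}
    if mined:
        hits = sum(1 for r in mined if (r.key, r.direction) in planted_keys)
        precision = hits / len(mined)
    else:
        precision = None
    return RecoveryReport(n_planted, len(mined), recovered, recall, precision)
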