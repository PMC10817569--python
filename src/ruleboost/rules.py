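"""Conjunctive rule mining, the curated knowledge base, and probability
adjustment.

A rule is ``IF <conjunction of up to three literals> THEN raise (or lower)
the predicted event probability``.  Candidate rules are mined exhaustively
from the imputed cohort by scoring every antecedent's subgroup event rate
against the baseline rate; survivors are ranked low/medium/high (by effect
size, or by an editable curation file standing in for expert review) and
capped to a small knowledge base.  At prediction time each fired rule adds
a signed per-rank offset to the base model's log-odds, which keeps the
adjusted probability inside (0, 1) and makes opposite-direction rules of
equal rank cancel exactly.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import CohortTable, CohortError

RANK_ORDER = ("low", "medium", "high")
DEFAULT_RANK_DELTAS = {"low": 0.4, "medium": 0.8, "high": 1.2}
PROB_EPS = 1e-6


class RuleError(ValueError):
    """Raised when a rule or knowledge base violates its contract."""


@dataclass(frozen=True, order=True)
class Literal:
    """One condition of an antecedent: a feature required to be 1 or 0.

    Negative polarity encodes protective "absence of" conditions.
    """

    feature_name: str
    polarity: int  # required value, 0 or 1

    def __post_init__(self):
        if self.polarity not in (0, 1):
            raise RuleError(f"polarity must be 0 or 1, got {self.polarity}")

    def __str__(self) -> str:
        return f"{self.feature_name}={self.polarity}"

    @classmethod
    def parse(cls, text: str) -> "Literal":
        name, _, value = text.rpartition("=")
        if not name or value not in ("0", "1"):
            raise RuleError(f"cannot parse literal {text!r}")
        return cls(name, int(value))


def antecedent_key(literals) -> str:
    """Canonical string for an antecedent, e.g. ``"f1=1 & f2=0"``."""
    return " & ".join(str(lit) for lit in sorted(literals))


@dataclass(frozen=True)
class RuleStats:
    """Mining-time evidence for a rule, kept for provenance."""

    support: int
    subgroup_rate: float
    baseline_rate: float
    effect_ratio: float
    usable: bool = True
    direction_tie: bool = False

    @property
    def strength(self) -> float:
        """Symmetric effect size max(ratio, 1/ratio); inf for zero subgroups."""
        r = self.effect_ratio
        if r == 0.0:
            return np.inf
        return max(r, 1.0 / r)


@dataclass(frozen=True)
class Rule:
    """A conjunctive antecedent with a direction, an optional rank and stats."""

    literals: tuple[Literal, ...]
    direction: str  # "increase" | "decrease"
    rank: str | None = None
    stats: RuleStats | None = None

    def __post_init__(self):
        if not 1 <= len(self.literals) <= 3:
            raise RuleError(f"rules take 1-3 literals, got {len(self.literals)}")
        names = [lit.feature_name for lit in self.literals]
        if len(set(names)) != len(names):
            raise RuleError(f"repeated feature in antecedent: {names}")
        if self.direction not in ("increase", "decrease"):
            raise RuleError(f"direction must be increase/decrease, got {self.direction!r}")
        if self.rank is not None and self.rank not in RANK_ORDER:
            raise RuleError(f"rank must be one of {RANK_ORDER}, got {self.rank!r}")

    @property
    def key(self) -> str:
        return antecedent_key(self.literals)

    @property
    def sign(self) -> int:
        return 1 if self.direction == "increase" else -1

    def fires(self, row) -> bool:
        return all(row[lit.feature_name] == lit.polarity for lit in self.literals)

    def fire_mask(self, frame: pd.DataFrame) -> np.ndarray:
        mask = np.ones(len(frame), dtype=bool)
        for lit in self.literals:
            mask &= frame[lit.feature_name].to_numpy() == lit.polarity
        return mask


@dataclass(frozen=True)
class RuleKB:
    """The curated knowledge base: ranked rules plus rank -> log-odds offsets."""

    rules: tuple[Rule, ...]
    rank_deltas: dict[str, float]
    max_rules: int = 20

    def __post_init__(self):
        if len(self.rules) > self.max_rules:
            raise RuleError(f"{len(self.rules)} rules exceed cap {self.max_rules}")
        deltas = [self.rank_deltas.get(r) for r in RANK_ORDER]
        if any(d is None or d <= 0 for d in deltas):
            raise RuleError(f"rank_deltas must be positive for {RANK_ORDER}")
        if not deltas[0] < deltas[1] < deltas[2]:
            raise RuleError(f"rank_deltas must increase low < medium < high: {deltas}")
        for rule in self.rules:
            if rule.rank is None:
                raise RuleError(f"KB rule {rule.key!r} lacks a rank")

    def feature_names(self) -> list[str]:
        names = {lit.feature_name for rule in self.rules for lit in rule.literals}
        return sorted(names)

    def signed_offsets(self, frame: pd.DataFrame) -> np.ndarray:
        """Total signed log-odds adjustment per row of ``frame``."""
        missing = [f for f in self.feature_names() if f not in frame.columns]
        if missing:
            raise RuleError(f"rows lack KB features: {missing}")
        total = np.zeros(len(frame))
        for rule in self.rules:
            delta = self.rank_deltas[rule.rank]
            total += rule.fire_mask(frame) * rule.sign * delta
        return total

    # -- serialization ---------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "max_rules": self.max_rules,
            "rank_deltas": {r: self.rank_deltas[r] for r in RANK_ORDER},
            "rules": [_rule_to_dict(rule) for rule in self.rules],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RuleKB":
        with open(path) as fh:
            payload = json.load(fh)
        rules = tuple(_rule_from_dict(d) for d in payload["rules"])
        return cls(rules, payload["rank_deltas"], payload.get("max_rules", 20))

    def to_csv(self, path) -> None:
        rows = []
        for rule in self.rules:
            lits = [str(lit) for lit in rule.literals] + [""] * (3 - len(rule.literals))
            rows.append(lits + [rule.direction, rule.rank])
        frame = pd.DataFrame(
            rows, columns=["literal_1", "literal_2", "literal_3", "direction", "rank"]
        )
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, rank_deltas=None, max_rules: int = 20) -> "RuleKB":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        rules = []
        for _, row in frame.iterrows():
            lits = tuple(
                Literal.parse(row[c])
                for c in ("literal_1", "literal_2", "literal_3")
                if row[c].strip()
            )
            rules.append(Rule(lits, row["direction"], row["rank"]))
        return cls(tuple(rules), dict(rank_deltas or DEFAULT_RANK_DELTAS), max_rules)


def _rule_to_dict(rule: Rule) -> dict:
    d = {
        "literals": [str(lit) for lit in rule.literals],
        "direction": rule.direction,
        "rank": rule.rank,
    }
    if rule.stats is not None:
        d["stats"] = {
            "support": rule.stats.support,
            "subgroup_rate": rule.stats.subgroup_rate,
            "baseline_rate": rule.stats.baseline_rate,
            "effect_ratio": rule.stats.effect_ratio,
        }
    return d


def _rule_from_dict(d: dict) -> Rule:
    stats = None
    if "stats" in d:
        stats = RuleStats(
            support=d["stats"]["support"],
            subgroup_rate=d["stats"]["subgroup_rate"],
            baseline_rate=d["stats"]["baseline_rate"],
            effect_ratio=d["stats"]["effect_ratio"],
        )
    lits = tuple(Literal.parse(s) for s in d["literals"])
    return Rule(lits, d["direction"], d.get("rank"), stats)


# -- mining --------------------------------------------------------------------


def enumerate_antecedents(feature_names, max_arity: int = 3, polarities: str = "both"):
    """Yield every antecedent of 1..max_arity distinct features.

    With ``polarities="both"`` each chosen feature may be required present
    or absent; ``"positive_only"`` restricts to presence.  Order is
    deterministic: by arity, then feature combination, then polarity
    pattern.
    """
    names = list(feature_names)
    if max_arity < 1:
        raise RuleError(f"max_arity must be >= 1, got {max_arity}")
    if max_arity > len(names):
        raise RuleError(f"max_arity {max_arity} exceeds {len(names)} features")
    if polarities not in ("both", "positive_only"):
        raise RuleError(f"unknown polarities mode {polarities!r}")
    pol_values = (1, 0) if polarities == "both" else (1,)
    for arity in range(1, max_arity + 1):
        for combo in itertools.combinations(names, arity):
            for pols in itertools.product(pol_values, repeat=arity):
                yield tuple(Literal(f, p) for f, p in zip(combo, pols))


def score_antecedent(antecedent, t: CohortTable) -> Rule:
    """Score one antecedent on an imputed cohort.

    Returns a provisional :class:`Rule` whose direction follows the sign of
    (subgroup event rate - baseline rate); zero-support antecedents come
    back flagged unusable.
    """
    if t.n_missing:
        raise CohortError("score_antecedent requires an imputed cohort")
    literals = tuple(antecedent)
    mask = np.ones(t.n_patients, dtype=bool)
    for lit in literals:
        if lit.feature_name not in t.features.columns:
            raise RuleError(f"unknown feature {lit.feature_name!r}")
        mask &= t.features[lit.feature_name].to_numpy() == lit.polarity
    support = int(mask.sum())
    y = t.outcome.to_numpy()
    baseline = float(y.mean())
    if support == 0:
        stats = RuleStats(0, np.nan, baseline, np.nan, usable=False)
        return Rule(literals, "increase", stats=stats)
    subgroup = float(y[mask].mean())
    ratio = subgroup / baseline if baseline > 0 else np.nan
    tie = subgroup == baseline
    direction = "increase" if subgroup > baseline else "decrease"
    stats = RuleStats(support, subgroup, baseline, ratio, usable=True, direction_tie=tie)
    return Rule(literals, direction, stats=stats)


def mine_rules(
    t: CohortTable,
    min_support: int = 10,
    min_effect_ratio: float = 1.5,
    max_arity: int = 3,
    polarities: str = "both",
) -> list[Rule]:
    """Exhaustively score all antecedents and keep the strong, supported ones.

    A candidate survives when its support reaches ``min_support`` and its
    symmetric effect size max(ratio, 1/ratio) reaches ``min_effect_ratio``.
    Survivors sort by effect strength, then support, then antecedent text,
    so the candidate list is reproducible.
    """
    survivors = []
    arity = min(max_arity, len(t.feature_names))
    for antecedent in enumerate_antecedents(t.feature_names, arity, polarities):
        rule = score_antecedent(antecedent, t)
        s = rule.stats
        if not s.usable or s.direction_tie:
            continue
        if s.support >= min_support and s.strength >= min_effect_ratio:
            survivors.append(rule)
    survivors.sort(key=lambda r: (-r.stats.strength, -r.stats.support, r.key))
    return survivors


def assign_ranks(rules, mode: str = "auto", curation=None) -> list[Rule]:
    """Attach low/medium/high ranks to mined rules.

    ``auto`` splits the mined order (strongest first) into tertiles:
    top third -> high, middle -> medium, bottom -> low.  ``file`` reads the
    ranks from a curation mapping (antecedent key -> rank), the mechanism
    that stands in for expert clinical review; in auto mode a curation
    mapping may still override individual rules.
    """
    rules = list(rules)
    if not rules:
        raise RuleError("cannot rank an empty rule list")
    curation = dict(curation or {})
    unknown = set(curation) - {r.key for r in rules}
    if unknown:
        raise RuleError(f"curation references unmined rules: {sorted(unknown)}")
    ranked = []
    n = len(rules)
    for i, rule in enumerate(rules):
        if rule.key in curation:
            rank = curation[rule.key]
            if rank not in RANK_ORDER:
                raise RuleError(f"invalid curated rank {rank!r} for {rule.key!r}")
        elif mode == "file":
            raise RuleError(f"file mode: no curated rank for {rule.key!r}")
        else:
            rank = "high" if i < n / 3 else ("medium" if i < 2 * n / 3 else "low")
        ranked.append(replace(rule, rank=rank))
    return ranked


def select_kb(ranked_rules, max_rules: int = 20, rank_deltas=None) -> RuleKB:
    """Cap the ranked candidates to the strongest ``max_rules`` rules."""
    kept = tuple(ranked_rules[:max_rules])
    return RuleKB(kept, dict(rank_deltas or DEFAULT_RANK_DELTAS), max_rules)


def apply_rules(kb: RuleKB, patient_row, p_base: float) -> float:
    """Adjust one base probability by the fired rules of the knowledge base.

    The base probability is clipped away from 0/1, moved to log-odds, each
    fired rule adds its signed per-rank offset, and the sum maps back
    through the logistic function.
    """
    p = float(np.clip(p_base, PROB_EPS, 1.0 - PROB_EPS))
    offset = 0.0
    for rule in kb.rules:
        for lit in rule.literals:
            if lit.feature_name not in patient_row:
                raise RuleError(f"patient row lacks KB feature {lit.feature_name!r}")
        if rule.fires(patient_row):
            offset += rule.sign * kb.rank_deltas[rule.rank]
    return float(expit(logit(p) + offset))


def apply_rules_frame(kb: RuleKB, frame: pd.DataFrame, p_base) -> np.ndarray:
    """Vectorized :func:`apply_rules` over a frame of complete patient rows."""
    p = np.clip(np.asarray(p_base, dtype=float), PROB_EPS, 1.0 - PROB_EPS)
    return expit(logit(p) + kb.signed_offsets(frame))
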