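"""Binary patient cohorts: reading, validation, preprocessing and splitting.

A cohort is a table of patients by binary clinical features (0 = absent,
1 = present, NaN = not recorded) together with one binary outcome column
(1 = adverse event).  All preprocessing the downstream pipeline relies on
lives here: removal of constant features, mode imputation fitted on a
training partition, and reproducible random train/test splits.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Cell contents accepted as "missing" when reading a cohort CSV.
DEFAULT_MISSING_TOKENS = ("", "NA", "NaN")


class CohortError(ValueError):
    """Raised when a cohort violates its contract (non-binary cells, ...)."""


@dataclass(frozen=True)
class CohortTable:
    """Patients x binary features plus one binary outcome vector.

    Parameters
    ----------
    features : pandas.DataFrame
        Float-typed frame holding 0.0, 1.0 or NaN (missing); the index
        carries opaque patient identifiers.
    outcome : pandas.Series
        Integer 0/1 vector aligned with ``features``; never missing.
    """

    features: pd.DataFrame
    outcome: pd.Series

    def __post_init__(self) -> None:
        if len(self.features) < 1:
            raise CohortError("cohort must contain at least one row")
        if not self.features.index.equals(self.outcome.index):
            raise CohortError("features and outcome are not aligned")
        if self.features.columns.duplicated().any():
            dupes = self.features.columns[self.features.columns.duplicated()]
            raise CohortError(f"duplicate feature names: {sorted(set(dupes))}")
        vals = self.features.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            bad = sorted(set(vals[~ok].tolist()))
            raise CohortError(f"non-binary feature values: {bad}")
        out = self.outcome.to_numpy()
        if pd.isna(out).any():
            raise CohortError("outcome contains missing values")
        if not np.isin(out, (0, 1)).all():
            bad = sorted(set(np.asarray(out)[~np.isin(out, (0, 1))].tolist()))
            raise CohortError(f"non-binary outcome values: {bad}")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_patients(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def n_missing(self) -> int:
        return int(self.features.isna().to_numpy().sum())

    def subset_rows(self, index) -> "CohortTable":
        return CohortTable(self.features.loc[index], self.outcome.loc[index])

    def subset_features(self, names) -> "CohortTable":
        missing = [n for n in names if n not in self.features.columns]
        if missing:
            raise CohortError(f"unknown features: {missing}")
        return CohortTable(self.features.loc[:, list(names)], self.outcome)

    def content_hash(self) -> str:
        """Stable hash of the cohort contents, used in run manifests."""
        h = hashlib.sha256()
        h.update(pd.util.hash_pandas_object(self.features.fillna(-1)).to_numpy().tobytes())
        h.update(pd.util.hash_pandas_object(self.outcome).to_numpy().tobytes())
        h.update(",".join(map(str, self.features.columns)).encode())
        return h.hexdigest()


@dataclass(frozen=True)
class ModeMap:
    """Per-feature most frequent non-missing value, with tie flags.

    Fitted on one table (normally the training part of a split) and applied
    to another; ties between 0 and 1 resolve to 0, the majority value in a
    sparse cohort, and are flagged.
    """

    modes: dict[str, int]
    ties: dict[str, bool]


@dataclass(frozen=True)
class SplitPair:
    """A train/test partition of a cohort, reproducible from its seed."""

    train: CohortTable
    test: CohortTable
    seed: int
    fraction_test: float
    n_redraws: int = 0


def read_cohort(
    path,
    outcome_column: str = "events",
    missing_tokens=DEFAULT_MISSING_TOKENS,
) -> CohortTable:
    """Read a cohort CSV with binary cells and one binary outcome column.

    Cells equal to any of ``missing_tokens`` become missing; any other cell
    must parse as 0 or 1.  The outcome column must be strictly binary.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if outcome_column not in raw.columns:
        raise CohortError(f"outcome column {outcome_column!r} not in {path}")
    tokens = set(missing_tokens)

    def _parse(col: pd.Series, allow_missing: bool) -> pd.Series:
        stripped = col.str.strip()
        out = pd.Series(np.nan, index=col.index, dtype=float)
        is_missing = stripped.isin(tokens)
        if is_missing.any() and not allow_missing:
            raise CohortError(f"missing values in outcome column {col.name!r}")
        present = ~is_missing
        numeric = pd.to_numeric(stripped[present], errors="coerce")
        bad = numeric.isna() | ~numeric.isin((0, 1))
        if bad.any():
            bad_vals = sorted(set(stripped[present][bad]))
            raise CohortError(f"non-binary values in column {col.name!r}: {bad_vals}")
        out[present] = numeric
        return out

    outcome = _parse(raw[outcome_column], allow_missing=False).astype(int)
    features = raw.drop(columns=[outcome_column]).apply(_parse, allow_missing=True)
    return CohortTable(features, outcome)


def write_cohort(t: CohortTable, path, outcome_column: str = "events") -> None:
    """Write a cohort back to CSV; missing cells become empty fields."""
    frame = t.features.copy()
    frame[outcome_column] = t.outcome
    with open(path, "w", newline="") as fh:
        frame.to_csv(
            fh, index=False,
            float_format="%.0f", na_rep="",
        )


def drop_constant_features(t: CohortTable) -> tuple[CohortTable, list[str]]:
    """Remove features with fewer than two distinct observed values.

    A feature whose non-missing values are all identical carries no signal
    regardless of its missing cells, so it counts as constant too.  The
    removed names keep their original column order.
    """
    removed = [c for c in t.features.columns if t.features[c].nunique(dropna=True) < 2]
    if len(removed) == len(t.features.columns):
        raise CohortError(f"all features constant: {removed}")
    if removed:
        logger.info("dropping %d constant features: %s", len(removed), removed)
    kept = t.features.drop(columns=removed)
    return CohortTable(kept, t.outcome), removed


def fit_mode(t: CohortTable) -> ModeMap:
    """Most frequent non-missing value per feature; 0/1 ties go to 0."""
    modes: dict[str, int] = {}
    ties: dict[str, bool] = {}
    for name in t.features.columns:
        col = t.features[name]
        n1 = int((col == 1.0).sum())
        n0 = int((col == 0.0).sum())
        if n0 + n1 == 0:
            raise CohortError(f"feature {name!r} is entirely missing")
        modes[name] = 1 if n1 > n0 else 0
        ties[name] = n1 == n0
    return ModeMap(modes, ties)


def impute(t: CohortTable, m: ModeMap) -> CohortTable:
    """Replace missing cells with the fitted per-feature mode."""
    absent = [c for c in t.features.columns if c not in m.modes]
    if absent:
        raise CohortError(f"features not covered by mode map: {absent}")
    filled = t.features.fillna({c: float(m.modes[c]) for c in t.features.columns})
    return CohortTable(filled, t.outcome)


def split_cohort(
    t: CohortTable,
    fraction_test: float = 0.2,
    seed: int = 0,
    max_redraws: int = 100,
) -> SplitPair:
    """Uniform random train/test partition with ``floor(fraction_test * n)``
    test rows, deterministic for a given seed.

    One-class test sets leave MCC and AUC undefined, so a draw whose test
    part lacks either outcome class is redrawn under an incremented
    sub-seed; each redraw is logged.
    """
    if not 0.0 < fraction_test < 1.0:
        raise CohortError(f"fraction_test must lie in (0,1), got {fraction_test}")
    n = t.n_patients
    if n < 2:
        raise CohortError("need at least 2 rows to split")
    n_test = int(np.floor(fraction_test * n))
    if n_test < 1:
        raise CohortError(f"fraction_test {fraction_test} yields an empty test set")
    for attempt in range(max_redraws + 1):
        rng = np.random.default_rng([int(seed) % 2**31, attempt])
        perm = rng.permutation(n)
        test_idx = t.features.index[np.sort(perm[:n_test])]
        train_idx = t.features.index[np.sort(perm[n_test:])]
        test_out = t.outcome.loc[test_idx]
        if test_out.nunique() == 2:
            if attempt:
                logger.info("split seed %d: accepted after %d redraw(s)", seed, attempt)
            return SplitPair(
                train=t.subset_rows(train_idx),
                test=t.subset_rows(test_idx),
                seed=seed,
                fraction_test=fraction_test,
                n_redraws=attempt,
            )
        logger.info("split seed %d attempt %d: one-class test set, redrawing", seed, attempt)
    raise CohortError(
        f"could not draw a two-class test set in {max_redraws} redraws; "
        "outcome distribution is degenerate"
    )


def describe_cohort(t: CohortTable, outcome_column: str = "events") -> pd.DataFrame:
    """Per-feature count and percentage of 1s among non-missing values.

    The outcome appears as the last row; percentages use the number of
    non-missing observations of each variable as denominator.
    """
    rows = []
    for name in t.features.columns:
        col = t.features[name]
        n_obs = int(col.notna().sum())
        n_pos = int((col == 1.0).sum())
        pct = 100.0 * n_pos / n_obs if n_obs else 0.0
        rows.append((name, n_obs, n_pos, pct))
    n = t.n_patients
    n_events = int(t.outcome.sum())
    rows.append((outcome_column, n, n_events, 100.0 * n_events / n))
    return pd.DataFrame(rows, columns=["variable", "n_observed", "n_positive", "pct_positive"])
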