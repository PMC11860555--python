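"""Label generation from state-anxiety scores, subset assembly, and class
rebalancing by majority-class undersampling.

Labels dichotomize the 6-item short-form state-anxiety score (range 6-24) at
a cutoff of 11; a boundary score counts as anxious (``>= cutoff``), with a
``strict`` flag for the alternative reading.  Undersampling removes randomly
chosen majority rows only — every minority row is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "LabelSpec",
    "BalanceReport",
    "label_from_stai",
    "undersample",
    "assemble_subsets",
]

#: the in-the-wild subset is rebalanced to these minority fractions
WILD_TARGET_FRACTIONS = (0.30, 0.41)


@dataclass
class LabelSpec:
    cutoff: int = 11
    low: int = 6
    high: int = 24
    strict: bool = False  # True: anxious iff score > cutoff

    def __post_init__(self) -> None:
        if not (self.low <= self.cutoff <= self.high):
            raise InvalidParameterError("cutoff outside score range")


@dataclass
class BalanceReport:
    before: dict[int, int]
    after: dict[int, int]
    target_minority_frac: float
    n_removed: int
    seed: int | None = None
    notes: list[str] = field(default_factory=list)


def label_from_stai(score: int, spec: LabelSpec | None = None) -> int:
    """1 (anxious) iff the score reaches the cutoff, else 0."""
    spec = spec or LabelSpec()
    score = int(score)
    if not (spec.low <= score <= spec.high):
        raise InvalidInputError(f"score {score} outside [{spec.low}, {spec.high}]")
    if spec.strict:
        return int(score > spec.cutoff)
    return int(score >= spec.cutoff)


def undersample(table: pd.DataFrame, target_minority_frac: float, seed: int = 0,
                label_col: str = "label", group_col: str | None = None
                ) -> tuple[pd.DataFrame, BalanceReport]:
    """Reduce the majority class to hit a target minority fraction.

    Keeps ``round(n_min * (1 - p) / p)`` majority rows, sampled uniformly
    without replacement (seeded); the minority class is untouched.  With
    ``group_col`` set, sampling is stratified by that column (e.g. subject)
    so no group is disproportionately discarded.
    """
    if not (0 < target_minority_frac < 1):
        raise InvalidParameterError("target_minority_frac must lie in (0, 1)")
    counts = table[label_col].value_counts()
    if len(counts) < 2:
        raise InvalidInputError("both classes must be present")
    minority = counts.idxmin()
    majority = counts.idxmax()
    n_min, n_maj = int(counts[minority]), int(counts[majority])
    p = target_minority_frac
    keep = int(round(n_min * (1.0 - p) / p))
    if keep > n_maj:
        raise InvalidParameterError(
            f"target minority fraction {p} is below the current fraction "
            f"{n_min / (n_min + n_maj):.4f}")
    before = {int(k): int(v) for k, v in counts.items()}
    if keep == n_maj:
        report = BalanceReport(before=before, after=dict(before),
                               target_minority_frac=p, n_removed=0, seed=seed,
                               notes=["already at target"])
        return table.copy(), report
    rng = np.random.default_rng(seed)
    maj_idx = table.index[table[label_col] == majority].to_numpy()
    if group_col is not None:
        kept_parts = []
        groups = table.loc[maj_idx].groupby(group_col).groups
        quota = keep / len(maj_idx)
        for _, idx in sorted(groups.items()):
            idx = np.asarray(idx)
            k = int(round(len(idx) * quota))
            kept_parts.append(rng.choice(idx, size=min(k, len(idx)), replace=False))
        kept_maj = np.concatenate(kept_parts) if kept_parts else np.array([], int)
    else:
        kept_maj = rng.choice(maj_idx, size=keep, replace=False)
    keep_mask = table[label_col].eq(minority).to_numpy()
    keep_mask[table.index.get_indexer(kept_maj)] = True
    out = table.loc[keep_mask].copy()
    after = {int(k): int(v) for k, v in out[label_col].value_counts().items()}
    return out, BalanceReport(before=before, after=after,
                              target_minority_frac=p,
                              n_removed=n_maj - int(after.get(int(majority), 0)),
                              seed=seed)


def assemble_subsets(tables: dict[str, pd.DataFrame] | pd.DataFrame, seed: int = 0
                     ) -> dict[str, pd.DataFrame]:
    """Assemble the analysis subsets from subset-tagged feature tables.

    ``calibration`` and ``in_lab`` pass through untouched.  ``in_the_wild``
    is returned raw plus rebalanced variants at 30% and 41% minority
    fraction (keys ``in_the_wild_30`` and ``in_the_wild_41``).
    """
    if isinstance(tables, pd.DataFrame):
        if "subset" not in tables.columns:
            raise InvalidInputError("feature table lacks a 'subset' column")
        tables = {str(s): t.reset_index(drop=True)
                  for s, t in tables.groupby("subset")}
    out: dict[str, pd.DataFrame] = {}
    for name, table in tables.items():
        if table.empty:
            raise InvalidInputError(f"subset {name!r} is empty")
        if name not in ("calibration", "in_lab", "in_the_wild"):
            raise InvalidInputError(f"unknown subset tag {name!r}")
        out[name] = table
        if name == "in_the_wild":
            for p in WILD_TARGET_FRACTIONS:
                balanced, _ = undersample(table.reset_index(drop=True), p, seed=seed)
                out[f"in_the_wild_{int(round(p * 100))}"] = balanced
    return out
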