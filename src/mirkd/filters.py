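"""Candidate-selection filter cascade and fold-change categorization.

The selection procedure for knockdown-responsive miRNAs is a cascade of
fold-change filters rather than a count-based statistical test:

1. *Parental concordance* — features whose mean expression differs more than
   2-fold between the two parental control genotypes are excluded (the two
   controls must agree before they can be grouped into one control set).
2. *Replicate concordance* — features whose expression differs more than
   2-fold between biological replicates of the same genotype are excluded.
3. *Candidate selection* — a feature is a candidate only if its knockdown
   mean changes at least 2-fold against EVERY individual parental replicate;
   the fold change against the grouped control (mean of all four parental
   replicates) is recorded alongside.

Fold changes use the signed convention throughout: a ratio r >= 1 is
reported as +r, a ratio r < 1 as -1/r (a halving is -2.0), so |fc| >= 1
always.  Concordance filters are strict (> threshold excludes); the
candidate and category thresholds are inclusive (>= threshold passes).

A whitelist provides an explicit, logged override for features that fail the
concordance filters but are retained anyway — reproducing the kind of
documented exception studies make for their strongest hit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .quantify import ExpressionTable

__all__ = [
    "PipelineConfig",
    "FoldChangeRecord",
    "CategorySummary",
    "ConcordanceResult",
    "signed_fold_change",
    "parental_concordance",
    "replicate_concordance",
    "candidate_selection",
    "categorize",
    "categorize_all",
]

CATEGORIES = ("unchanged", "up_1.5", "down_1.5", "up_2", "down_2")


@dataclass
class PipelineConfig:
    """Thresholds and options of the filter cascade.

    concordance_threshold
        Fold difference above which parental/replicate disagreement excludes
        a feature (strict >).
    candidate_threshold
        Minimum fold change, against every parental replicate, for a feature
        to become a candidate (inclusive >=).
    category_thresholds
        The two category cut points (default 1.5 and 2), inclusive.
    pseudocount
        Added to numerator and denominator of every ratio; default 0 with an
        explicit error on 0/0 (the analyzed universe normally has >1 read
        everywhere, so zeros indicate an upstream problem).
    alpha
        Two-sided significance level used wherever a t-test backs a
        significance call.
    whitelist
        Feature ids retained through the concordance filters regardless of
        outcome, flagged ``whitelisted=True``.
    """

    concordance_threshold: float = 2.0
    candidate_threshold: float = 2.0
    category_thresholds: tuple[float, float] = (1.5, 2.0)
    pseudocount: float = 0.0
    alpha: float = 0.05
    whitelist: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.whitelist = frozenset(self.whitelist)
        if self.concordance_threshold <= 1 or self.candidate_threshold <= 1:
            raise ValueError("fold thresholds must be > 1")
        lo, hi = self.category_thresholds
        if not 1 < lo <= hi:
            raise ValueError("category_thresholds must be > 1 and ordered")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")


@dataclass(frozen=True)
class FoldChangeRecord:
    """Per-feature result of the cascade: fold change, category, provenance."""

    feature_id: str
    mean_control: float
    mean_knockdown: float
    signed_fc: float
    category: str
    passed_filters: Mapping[str, bool] = field(default_factory=dict)
    whitelisted: bool = False


@dataclass(frozen=True)
class ConcordanceResult:
    retained: frozenset[str]
    excluded: frozenset[str]
    whitelisted: frozenset[str]
    fold_changes: pd.Series  # worst-case signed fc behind each decision


@dataclass(frozen=True)
class CategorySummary:
    """Counts and percentages of the three mutually exclusive top-level bins.

    ``up_1.5`` / ``down_1.5`` are inclusive of the stronger ``up_2`` /
    ``down_2`` subsets; unchanged + up_1.5 + down_1.5 = n_total.
    Percentages are of n_total, rounded to one decimal place.
    """

    n_total: int
    counts: Mapping[str, int]
    percentages: Mapping[str, float]


def signed_fold_change(mean_test: float, mean_ref: float, pseudocount: float = 0.0) -> float:
    """Signed fold change of test over reference.

    Returns r = (test+pc)/(ref+pc) when r >= 1, else -1/r.  A zero on one
    side (with pseudocount 0) yields +/-inf; both sides zero is undefined.
    """
    if mean_test < 0 or mean_ref < 0:
        raise ValueError("means must be non-negative")
    a = mean_test + pseudocount
    b = mean_ref + pseudocount
    if a == 0 and b == 0:
        raise ValueError("fold change undefined: both means zero (add a pseudocount)")
    if a >= b:
        return math.inf if b == 0 else a / b
    return -math.inf if a == 0 else -b / a


def _genotype_samples(design: pd.DataFrame, genotype: str) -> list[str]:
    sel = design[design["genotype"] == genotype]
    return list(sel["sample_id"])


def parental_concordance(expr: ExpressionTable, config: PipelineConfig) -> ConcordanceResult:
    """Exclude features discordant between the two parental genotype means.

    A feature is excluded iff |signed_fc(parent_A mean, parent_B mean)| is
    strictly greater than ``concordance_threshold``.  Whitelisted features
    are retained regardless and flagged.
    """
    a_samples = _genotype_samples(expr.design, "parent_A")
    b_samples = _genotype_samples(expr.design, "parent_B")
    if not a_samples or not b_samples:
        raise ValueError("both parental genotypes (parent_A, parent_B) must be present")
    mean_a = expr.values[a_samples].mean(axis=1)
    mean_b = expr.values[b_samples].mean(axis=1)
    fc = pd.Series(
        [
            signed_fold_change(mean_a[f], mean_b[f], config.pseudocount)
            for f in expr.values.index
        ],
        index=expr.values.index,
    )
    discordant = fc.abs() > config.concordance_threshold
    whitelisted = frozenset(f for f in expr.values.index[discordant] if f in config.whitelist)
    excluded = frozenset(expr.values.index[discordant]) - whitelisted
    retained = frozenset(expr.values.index) - excluded
    return ConcordanceResult(retained, excluded, whitelisted, fc)


def replicate_concordance(expr: ExpressionTable, config: PipelineConfig) -> ConcordanceResult:
    """Exclude features whose replicates disagree >threshold within any genotype."""
    index = expr.values.index
    worst = pd.Series(1.0, index=index)
    any_pair = False
    for genotype in expr.design["genotype"].unique():
        samples = _genotype_samples(expr.design, genotype)
        if len(samples) < 2:
            warnings.warn(
                f"genotype {genotype!r} has a single replicate; replicate "
                "concordance not assessable there",
                stacklevel=2,
            )
            continue
        any_pair = True
        sub = expr.values[samples] + config.pseudocount
        ratio = sub.max(axis=1) / sub.min(axis=1)
        worst = pd.concat([worst, ratio], axis=1).max(axis=1)
    if not any_pair:
        return ConcordanceResult(frozenset(index), frozenset(), frozenset(), worst)
    discordant = worst > config.concordance_threshold
    whitelisted = frozenset(f for f in index[discordant] if f in config.whitelist)
    excluded = frozenset(index[discordant]) - whitelisted
    return ConcordanceResult(frozenset(index) - excluded, excluded, whitelisted, worst)


def candidate_selection(
    expr: ExpressionTable,
    config: PipelineConfig,
    features: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Score each feature against every individual parental replicate.

    Returns a DataFrame indexed by feature with columns:

    - ``mean_knockdown``, ``mean_control`` (grouped mean of all parental
      replicates)
    - ``grouped_fc`` — signed fold change knockdown vs grouped control
    - ``min_abs_fc`` — the smallest |signed fc| of knockdown mean vs any
      single parental replicate (the binding constraint)
    - ``candidate`` — True iff min_abs_fc >= candidate_threshold
    """
    kd_samples = _genotype_samples(expr.design, "knockdown")
    parent_samples = _genotype_samples(expr.design, "parent_A") + _genotype_samples(
        expr.design, "parent_B"
    )
    if not kd_samples or not parent_samples:
        raise ValueError("design must contain knockdown and parental samples")
    index = pd.Index(list(features), name="feature_id") if features is not None else expr.values.index
    rows = []
    for f in index:
        kd_mean = float(expr.values.loc[f, kd_samples].mean())
        ctrl_vals = expr.values.loc[f, parent_samples].astype(float)
        grouped_fc = signed_fold_change(kd_mean, float(ctrl_vals.mean()), config.pseudocount)
        per_rep = [
            abs(signed_fold_change(kd_mean, float(v), config.pseudocount)) for v in ctrl_vals
        ]
        min_abs = min(per_rep)
        rows.append(
            {
                "mean_knockdown": kd_mean,
                "mean_control": float(ctrl_vals.mean()),
                "grouped_fc": grouped_fc,
                "min_abs_fc": min_abs,
                "candidate": min_abs >= config.candidate_threshold,
            }
        )
    return pd.DataFrame(rows, index=index)


def categorize(signed_fc: float, config: PipelineConfig | None = None) -> str:
    """Finest category label for one signed fold change."""
    config = config or PipelineConfig()
    lo, hi = config.category_thresholds
    if abs(signed_fc) < lo:
        return "unchanged"
    direction = "up" if signed_fc > 0 else "down"
    bound = hi if abs(signed_fc) >= hi else lo
    return f"{direction}_{bound:g}"


def categorize_all(
    fold_changes: Mapping[str, float] | pd.Series, config: PipelineConfig | None = None
) -> CategorySummary:
    """Tabulate signed fold changes into the category summary.

    Counts unchanged (|fc| < low threshold), up/down >= low threshold
    (inclusive of the >= high-threshold subsets) and the subsets themselves;
    percentages are of all features, one decimal place.
    """
    config = config or PipelineConfig()
    fc = pd.Series(dict(fold_changes)) if not isinstance(fold_changes, pd.Series) else fold_changes
    n = len(fc)
    if n == 0:
        zero = {c: 0 for c in ("unchanged", "up_1.5", "down_1.5", "up_2", "down_2")}
        return CategorySummary(0, zero, {c: 0.0 for c in zero})
    lo, hi = config.category_thresholds
    lo_key, hi_key = f"{lo:g}", f"{hi:g}"
    counts = {
        "unchanged": int((fc.abs() < lo).sum()),
        f"up_{lo_key}": int(((fc >= lo)).sum()),
        f"down_{lo_key}": int(((fc <= -lo)).sum()),
        f"up_{hi_key}": int(((fc >= hi)).sum()),
        f"down_{hi_key}": int(((fc <= -hi)).sum()),
    }
    percentages = {k: round(100.0 * v / n, 1) for k, v in counts.items()}
    return CategorySummary(n, counts, percentages)


def build_records(
    selection: pd.DataFrame,
    config: PipelineConfig | None = None,
    passed_filters: Mapping[str, Mapping[str, bool]] | None = None,
    whitelisted: Iterable[str] = (),
) -> list[FoldChangeRecord]:
    """Assemble FoldChangeRecords from a candidate_selection table."""
    config = config or PipelineConfig()
    whitelisted = set(whitelisted)
    records = []
    for f, row in selection.iterrows():
        records.append(
            FoldChangeRecord(
                feature_id=f,
                mean_control=row["mean_control"],
                mean_knockdown=row["mean_knockdown"],
                signed_fc=row["grouped_fc"],
                category=categorize(row["grouped_fc"], config),
                passed_filters=dict(passed_filters.get(f, {})) if passed_filters else {},
                whitelisted=f in whitelisted,
            )
        )
    return records
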