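"""Relative quantification of qRT-PCR Ct tables by the ddCt method.

Per biological replicate, the target's mean technical Ct minus the
normalizer's mean technical Ct gives dCt; the fold change between a test and
a control group is 2^-(mean dCt_test - mean dCt_control), reported in the
same signed convention as the sequencing fold changes (a halving is -2.0).
Significance is a two-sided two-sample t-test on the per-replicate dCt
values — the scale on which the measurement noise is approximately additive.
Amplification efficiency is fixed at 2 (no efficiency correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .filters import signed_fold_change

__all__ = ["QpcrResult", "delta_ct", "ddct_fold_change", "relative_quantification"]

CT_COLUMNS = ("target_id", "normalizer_id", "genotype", "bio_replicate", "tech_replicate", "ct")


@dataclass(frozen=True)
class QpcrResult:
    target_id: str
    fold_change: float  # signed convention, test vs control
    p_value: float
    n_bio: int  # biological replicates per group (minimum of the two)
    normalizer_id: str


def _check_ct_table(table: pd.DataFrame) -> None:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")


def delta_ct(table: pd.DataFrame, target_id: str, normalizer_id: str) -> pd.DataFrame:
    """Per-(genotype, biological replicate) dCt = mean Ct(target) - mean Ct(normalizer).

    Technical replicates are averaged within each biological replicate before
    the subtraction.  Raises if any target replicate lacks matching
    normalizer wells.
    """
    _check_ct_table(table)
    tgt = table[table["target_id"] == target_id]
    nrm = table[table["target_id"] == normalizer_id]
    if tgt.empty:
        raise ValueError(f"no Ct rows for target {target_id!r}")
    key = ["genotype", "bio_replicate"]
    tgt_mean = tgt.groupby(key)["ct"].mean()
    nrm_mean = nrm.groupby(key)["ct"].mean()
    missing = tgt_mean.index.difference(nrm_mean.index)
    if len(missing):
        raise ValueError(
            f"missing normalizer ({normalizer_id!r}) wells for replicate(s): {list(missing)}"
        )
    out = (tgt_mean - nrm_mean.loc[tgt_mean.index]).rename("delta_ct").reset_index()
    return out


def ddct_fold_change(
    dct_test: np.ndarray, dct_control: np.ndarray
) -> tuple[float, float]:
    """Signed fold change and p-value from two groups of per-replicate dCt.

    fold = 2^-(mean dCt_test - mean dCt_control), reported as +r / -1/r;
    p from a two-sided two-sample t-test on the dCt values.
    """
    dct_test = np.asarray(dct_test, dtype=float)
    dct_control = np.asarray(dct_control, dtype=float)
    if len(dct_test) < 2 or len(dct_control) < 2:
        raise ValueError("each group needs at least 2 biological replicates")
    ddct = dct_test.mean() - dct_control.mean()
    ratio = 2.0 ** (-ddct)
    fold = signed_fold_change(ratio, 1.0)
    if dct_test.std() == 0 and dct_control.std() == 0:
        # noise-free groups: the t statistic degenerates
        p = 1.0 if ddct == 0 else 0.0
    else:
        p = float(stats.ttest_ind(dct_test, dct_control).pvalue)
    return fold, p


def relative_quantification(
    table: pd.DataFrame,
    target_id: str,
    normalizer_id: str,
    test_genotype: str = "knockdown",
    control_genotype: str = "control",
) -> QpcrResult:
    """End-to-end ddCt analysis of one target in a Ct table."""
    dct = delta_ct(table, target_id, normalizer_id)
    test = dct.loc[dct["genotype"] == test_genotype, "delta_ct"].to_numpy()
    control = dct.loc[dct["genotype"] == control_genotype, "delta_ct"].to_numpy()
    fold, p = ddct_fold_change(test, control)
    return QpcrResult(
        target_id=target_id,
        fold_change=fold,
        p_value=p,
        n_bio=min(len(test), len(control)),
        normalizer_id=normalizer_id,
    )
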