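"""Mature-vs-precursor mechanism classification for changed miRNAs.

A mature miRNA whose level changes after knockdown of a 3'-5' exoribonuclease
can do so for three distinct reasons, distinguishable by whether its
pri/pre-miRNA precursor moves with it:

- mature up, precursor unchanged  -> the nuclease normally *degrades* the
  mature species (post-transcriptional degradation);
- mature down, precursor unchanged -> the nuclease participates in
  *processing* the mature miRNA from its precursor (processing defect);
- mature and precursor both change -> the effect is transcriptional or
  otherwise indirect.

"Unchanged" precursor is encoded as non-significance of the precursor fold
change (no precursor threshold is imposed), and significance means a
two-sided two-sample t-test at the configured alpha on replicate-level
values.  The decision table is total: every combination of signs and
significance flags maps to exactly one call.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .filters import PipelineConfig

__all__ = [
    "MechanismCall",
    "classify",
    "classify_table",
    "load_validated_evidence",
    "MECHANISM_CLASSES",
]

MECHANISM_CLASSES = (
    "post_transcriptional_degradation",
    "processing_defect",
    "transcriptional_indirect",
    "unchanged",
)

EVIDENCE_COLUMNS = (
    "feature_id",
    "mature_fc",
    "mature_significant",
    "precursor_fc",
    "precursor_significant",
)


@dataclass(frozen=True)
class MechanismCall:
    """One feature's evidence and its regulatory-mode call."""

    feature_id: str
    mature_fc: float
    mature_significant: bool
    precursor_fc: float
    precursor_significant: bool
    call: str
    discordant: bool = False  # mature and precursor significant with opposite signs


def _check_signed(fc: float, label: str) -> None:
    if abs(fc) < 1:
        raise ValueError(
            f"{label} fold change {fc} is malformed: signed convention requires |fc| >= 1"
        )


def classify(
    mature_fc: float,
    mature_significant: bool,
    precursor_fc: float,
    precursor_significant: bool,
    config: PipelineConfig | None = None,
    feature_id: str = "",
) -> MechanismCall:
    """Apply the mature-vs-precursor decision table to one feature.

    - mature not significant -> ``unchanged``;
    - mature significant, precursor not -> ``post_transcriptional_degradation``
      if the mature change is up, ``processing_defect`` if down;
    - both significant -> ``transcriptional_indirect`` (with a discordance
      flag when the signs disagree — a combination with no obvious single
      mechanism, retained as indirect but flagged).
    """
    _check_signed(mature_fc, "mature")
    _check_signed(precursor_fc, "precursor")
    discordant = False
    if not mature_significant:
        call = "unchanged"
    elif not precursor_significant:
        call = (
            "post_transcriptional_degradation" if mature_fc > 0 else "processing_defect"
        )
    else:
        call = "transcriptional_indirect"
        discordant = (mature_fc > 0) != (precursor_fc > 0)
    return MechanismCall(
        feature_id=feature_id,
        mature_fc=mature_fc,
        mature_significant=bool(mature_significant),
        precursor_fc=precursor_fc,
        precursor_significant=bool(precursor_significant),
        call=call,
        discordant=discordant,
    )


def classify_table(
    evidence: pd.DataFrame, config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every row of an evidence table.

    ``evidence`` must carry the columns ``feature_id``, ``mature_fc``,
    ``mature_significant``, ``precursor_fc``, ``precursor_significant``.
    Returns the table with ``call`` and ``discordant`` columns appended, and
    a per-class count summary (order-independent, all classes present).
    """
    missing = [c for c in EVIDENCE_COLUMNS if c not in evidence.columns]
    if missing:
        raise ValueError(f"evidence table missing columns: {missing}")
    if evidence["feature_id"].duplicated().any():
        dupes = evidence.loc[evidence["feature_id"].duplicated(), "feature_id"].tolist()
        raise ValueError(f"duplicate feature ids in evidence table: {dupes}")
    calls = [
        classify(
            row.mature_fc,
            bool(row.mature_significant),
            row.precursor_fc,
            bool(row.precursor_significant),
            config,
            feature_id=row.feature_id,
        )
        for row in evidence.itertuples(index=False)
    ]
    out = evidence.copy()
    out["call"] = [c.call for c in calls]
    out["discordant"] = [c.discordant for c in calls]
    summary = {cls: int((out["call"] == cls).sum()) for cls in MECHANISM_CLASSES}
    return out, summary


def load_validated_evidence() -> pd.DataFrame:
    """Packaged evidence fixture for the seven qPCR-validated knockdown hits.

    Mature fold changes are the published qRT-PCR values for the validated
    miRNA set (miR-987-5p, miR-277-3p, miR-252-5p, miR-34-5p, miR-317-5p,
    miR-9b-3p, miR-982-5p).  Precursor fold-change *magnitudes* were never
    tabulated and are synthetic nominal values; only their direction and
    significance (precursor moved vs. stayed at baseline) carry information.
    """
    with resources.files("mirkd").joinpath("data/mechanism_evidence_synthetic.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["mature_significant"] = df["mature_significant"].astype(bool)
    df["precursor_significant"] = df["precursor_significant"].astype(bool)
    return df
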