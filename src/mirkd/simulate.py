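"""Synthetic small RNA-seq experiment generator with known ground truth.

Emulates a knockdown-vs-control miRNA profiling experiment in larval wing
imaginal discs: two parental control genotypes and one knockdown genotype,
two biological replicates each; 12–22 million reads per sample of which only
~1.12% derive from mature miRNAs (the remainder is a 2S-rRNA-like contaminant
that co-purifies within the 18–22 nt size selection); and a bimodal
mature-miRNA abundance distribution whose high mode sits ~100-fold above the
low mode.  Spiked effects carry per-feature mechanism labels (degradation of
the mature species, a processing defect, or an indirect transcriptional
change) so the downstream filter cascade and mechanism classifier can be
scored against truth.

Counts are drawn from a negative binomial (Gamma–Poisson) — the standard
noise family for RNA-seq replicates.  Precursor abundances are simulated as a
parallel count matrix standing in for pri/pre-miRNA qPCR measurements:
precursor means follow the spiked fold change only for transcriptional
(indirect) effects and stay at baseline for post-transcriptional degradation
and processing defects.

All randomness flows from the single ``SimulationConfig.seed`` through
independent per-stage streams, so regenerating any one artifact (reference,
counts, reads, Ct table) is reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .quantify import CountMatrix

__all__ = [
    "MiRNARecord",
    "Effect",
    "SimulationConfig",
    "default_design",
    "generate_reference",
    "baseline_expression",
    "simulate_experiment",
    "simulate_reads",
    "simulate_qpcr",
    "study_effects",
    "write_fastq",
    "write_reference_fasta",
    "load_reference_fasta",
]

GENOTYPES = ("parent_A", "parent_B", "knockdown")
MECHANISMS = (
    "post_transcriptional_degradation",
    "processing_defect",
    "transcriptional_indirect",
    "unchanged",
)

# Illumina TruSeq small RNA 3' adapter.
TRUSEQ_SMALL_RNA_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

# Drosophila 2S rRNA (30 nt), the dominant contaminant class retained by an
# 18-22 nt size selection; reads are drawn as 18-22 nt fragments of it, so
# the decoy survives size selection but never matches a mature miRNA.
RRNA_2S = "TGCTTGGACTACATATGGTTGAGGGTTGTA"

# A novel mature miRNA reported from wing-disc small RNA-seq (miR-11182-3p);
# kept as a convenient realistic fixture sequence.
NOVEL_MIRNA_MIR_11182_3P = "CACAUCGAUGUUUUUCCACCUC"

_DNA = np.array(list("ACGT"))


@dataclass(frozen=True)
class MiRNARecord:
    """A mature/precursor miRNA pair, the countable unit of the pipeline."""

    feature_id: str
    mature_seq: str
    precursor_seq: str
    arm: str  # "5p" or "3p"
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        mature = self.mature_seq.upper().replace("U", "T")
        precursor = self.precursor_seq.upper().replace("U", "T")
        if not set(mature) <= set("ACGT") or not set(precursor) <= set("ACGT"):
            raise ValueError(f"{self.feature_id}: sequences must be over A/C/G/T/U")
        if mature not in precursor:
            raise ValueError(f"{self.feature_id}: mature_seq must be a substring of precursor_seq")
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"{self.feature_id}: arm must be '5p' or '3p'")


@dataclass(frozen=True)
class Effect:
    """A spiked knockdown effect: signed fold change plus mechanism label.

    ``fold_change`` uses the signed convention (+r for an r-fold increase,
    -r for an r-fold decrease, so |fold_change| >= 1).
    """

    feature_id: str
    fold_change: float
    mechanism: str

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if abs(self.fold_change) < 1:
            raise ValueError("fold_change must use the signed convention (|fc| >= 1)")
        if self.mechanism == "unchanged" and abs(self.fold_change) != 1:
            raise ValueError("mechanism 'unchanged' requires |fold_change| == 1")

    @property
    def ratio(self) -> float:
        """Linear expression ratio knockdown/control."""
        f = self.fold_change
        return f if f >= 1 else -1.0 / f


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    The defaults encode the emulated study design: 109 detectable miRNAs,
    two abundance modes separated 100-fold, 12–22 million reads per sample,
    and a 1.12% mature-miRNA read fraction.
    """

    n_features: int = 109
    mixture_low_mean: float = 1.0
    mixture_high_mean: float = 100.0
    mixture_weights: tuple[float, float] = (0.8, 0.2)
    lognormal_sigma: float = 0.6  # natural-log sd within each abundance mode
    dispersion: float = 0.05  # NB overdispersion: var = mu + dispersion * mu^2
    library_size_range: tuple[float, float] = (12e6, 22e6)
    mirna_fraction: float = 0.0112
    precursor_depth: float = 1e5  # expected total precursor counts per sample
    effects: tuple[Effect, ...] = ()
    adapter_seq: str = TRUSEQ_SMALL_RNA_ADAPTER
    read_length: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        self.effects = tuple(self.effects)
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if min(self.mixture_low_mean, self.mixture_high_mean) <= 0:
            raise ValueError("mixture means must be positive")
        if not 0 < self.mirna_fraction < 1:
            raise ValueError("mirna_fraction must lie in (0, 1)")
        if self.lognormal_sigma < 0 or self.dispersion < 0:
            raise ValueError("lognormal_sigma and dispersion must be non-negative")
        w = self.mixture_weights
        if len(w) != 2 or min(w) < 0 or not math.isclose(sum(w), 1.0, rel_tol=1e-9):
            raise ValueError("mixture_weights must be two non-negative values summing to 1")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ValueError("library_size_range must satisfy 0 < low <= high")


# Per-stage RNG streams derived from the single config seed; spawning keys
# are positional, so adding a stage never perturbs earlier ones.
_STREAMS = ("reference", "baseline", "counts", "reads", "qpcr")


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.Generator(np.random.PCG64(children[_STREAMS.index(stream)]))


def default_design() -> pd.DataFrame:
    """The study design: 3 genotypes x 2 biological replicates = 6 samples."""
    rows = [
        {"sample_id": f"{g}_rep{r}", "genotype": g, "replicate": r}
        for g in GENOTYPES
        for r in (1, 2)
    ]
    return pd.DataFrame(rows)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_DNA, size=length))


def generate_reference(config: SimulationConfig) -> list[MiRNARecord]:
    """Draw a synthetic mature/precursor reference of ``n_features`` entries.

    Mature lengths are uniform over 18–22 nt; each mature sequence is embedded
    in a random precursor with 16–49 nt flanks on either side (precursors
    therefore span 50–120 nt).  Deterministic for a fixed seed.
    """
    rng = _rng(config, "reference")
    width = len(str(config.n_features))
    records = []
    for i in range(config.n_features):
        mature_len = int(rng.integers(18, 23))
        mature = _random_seq(rng, mature_len)
        left = _random_seq(rng, int(rng.integers(16, 50)))
        right = _random_seq(rng, int(rng.integers(16, 50)))
        records.append(
            MiRNARecord(
                feature_id=f"syn-mir-{i + 1:0{width}d}",
                mature_seq=mature,
                precursor_seq=left + mature + right,
                arm=str(rng.choice(["5p", "3p"])),
            )
        )
    return records


def baseline_expression(reference: Sequence[MiRNARecord], config: SimulationConfig) -> pd.DataFrame:
    """Per-feature baseline relative abundance from the two-mode log-normal mixture.

    Returns a DataFrame indexed by feature_id with columns ``mode`` ("low" or
    "high") and ``rel_mean`` (relative expected expression, arbitrary units).
    Uses its own RNG stream, so it reproduces exactly the baselines that
    :func:`simulate_experiment` will use for the same config.
    """
    rng = _rng(config, "baseline")
    n = len(reference)
    high = rng.random(n) < config.mixture_weights[1]
    mode_mean = np.where(high, config.mixture_high_mean, config.mixture_low_mean)
    rel = mode_mean * np.exp(rng.normal(0.0, config.lognormal_sigma, size=n))
    return pd.DataFrame(
        {"mode": np.where(high, "high", "low"), "rel_mean": rel},
        index=pd.Index([r.feature_id for r in reference], name="feature_id"),
    )


def _effect_maps(reference, config):
    ids = {r.feature_id for r in reference}
    mature_ratio: dict[str, float] = {}
    precursor_ratio: dict[str, float] = {}
    mechanism: dict[str, str] = {}
    for eff in config.effects:
        if eff.feature_id not in ids:
            raise ValueError(f"effect references unknown feature {eff.feature_id!r}")
        if eff.feature_id in mechanism:
            raise ValueError(f"duplicate effect for feature {eff.feature_id!r}")
        mechanism[eff.feature_id] = eff.mechanism
        mature_ratio[eff.feature_id] = eff.ratio
        # Precursor levels track the mature change only for indirect
        # transcriptional effects; direct degradation/processing effects
        # leave the precursor at baseline.
        precursor_ratio[eff.feature_id] = (
            eff.ratio if eff.mechanism == "transcriptional_indirect" else 1.0
        )
    return mature_ratio, precursor_ratio, mechanism


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-12)
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_experiment(
    reference: Sequence[MiRNARecord], config: SimulationConfig
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate mature and precursor count matrices with ground truth.

    Per-sample sequencing depth is uniform over ``library_size_range``; the
    expected mature-miRNA yield of a sample is depth x ``mirna_fraction``,
    allocated across features proportionally to their baseline relative
    means (times the spiked fold change in knockdown samples).  Precursor
    counts use the same relative abundances at ``precursor_depth``.

    Returns ``(mature_counts, precursor_counts, ground_truth, design)``.
    """
    reference = list(reference)
    base = baseline_expression(reference, config)
    mature_ratio, precursor_ratio, mechanism = _effect_maps(reference, config)
    design = default_design()
    rng = _rng(config, "counts")

    ids = base.index
    w = base["rel_mean"].to_numpy()
    w_frac = w / w.sum()
    mat_mult = np.array([mature_ratio.get(f, 1.0) for f in ids])
    pre_mult = np.array([precursor_ratio.get(f, 1.0) for f in ids])

    mature_cols, precursor_cols = {}, {}
    lo, hi = config.library_size_range
    for _, row in design.iterrows():
        depth = float(rng.uniform(lo, hi))
        kd = row["genotype"] == "knockdown"
        mu_mat = depth * config.mirna_fraction * w_frac * (mat_mult if kd else 1.0)
        mu_pre = config.precursor_depth * w_frac * (pre_mult if kd else 1.0)
        mature_cols[row["sample_id"]] = _nb_draw(rng, mu_mat, config.dispersion)
        precursor_cols[row["sample_id"]] = _nb_draw(rng, mu_pre, config.dispersion)

    mature = CountMatrix(pd.DataFrame(mature_cols, index=ids), design)
    precursor = CountMatrix(pd.DataFrame(precursor_cols, index=ids), design)
    truth = pd.DataFrame(
        {
            "true_fold_change": [_signed(mature_ratio.get(f, 1.0)) for f in ids],
            "mechanism": [mechanism.get(f, "unchanged") for f in ids],
            "mode": base["mode"],
        },
        index=ids,
    )
    return mature, precursor, truth, design


def _signed(ratio: float) -> float:
    return ratio if ratio >= 1 else -1.0 / ratio


def study_effects(
    reference: Sequence[MiRNARecord],
    config: SimulationConfig,
    up_folds: Sequence[float] = (49.5, 10.4, 4.2, 4.0, 4.0, 3.6, 3.4, 3.2, 3.1, 3.0, 3.0),
    down_folds: Sequence[float] = (-3.0, -3.2, -3.4, -3.6, -3.8, -4.0),
) -> tuple[Effect, ...]:
    """Spike a study-like effect set: 11 strong up- and 6 strong down-effects.

    Effects are placed on low-abundance-mode features (changed miRNAs in the
    emulated study were predominantly poorly expressed, and spiking the low
    mode keeps the library composition — hence per-million normalization —
    essentially unperturbed), restricted to the upper half of that mode:
    hits must be lowly but *reliably* expressed, with enough reads that
    counting noise does not dominate replicate comparisons.  One up-effect is
    labeled as post-transcriptional degradation of the mature species and one
    down-effect as a processing defect; all others are
    transcriptional/indirect.  Deterministic for a fixed config seed.
    """
    base = baseline_expression(reference, config)
    low = base[base["mode"] == "low"].sort_values("rel_mean")
    pool = list(low.index[len(low) // 2 :])  # upper half of the low mode
    n_needed = len(up_folds) + len(down_folds)
    if len(pool) < n_needed:
        pool = list(base.index)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((config.seed, 911))))
    chosen = list(rng.choice(pool, size=n_needed, replace=False))
    effects = []
    for i, f in enumerate(up_folds):
        mech = "post_transcriptional_degradation" if i == 2 else "transcriptional_indirect"
        effects.append(Effect(chosen[i], f, mech))
    for j, f in enumerate(down_folds):
        mech = "processing_defect" if j == 2 else "transcriptional_indirect"
        effects.append(Effect(chosen[len(up_folds) + j], f, mech))
    return tuple(effects)


def _decoy_reads(rng: np.random.Generator, n: int, adapter: str, read_length: int) -> list[str]:
    """n contaminant reads: 18-22 nt fragments of the 2S-rRNA-like decoy."""
    reads = []
    for _ in range(n):
        length = int(rng.integers(18, 23))
        start = int(rng.integers(0, len(RRNA_2S) - length + 1))
        frag = RRNA_2S[start : start + length]
        reads.append((frag + adapter)[:read_length])
    return reads


def simulate_reads(
    reference: Sequence[MiRNARecord],
    counts: CountMatrix,
    config: SimulationConfig,
) -> dict[str, list[str]]:
    """Expand a mature count matrix into per-sample raw read sets.

    Each mature read is the mature sequence with the 3' adapter appended,
    truncated to ``read_length``; per-feature read counts equal the count
    matrix exactly.  Contaminant (2S-rRNA-like) reads are added at proportion
    (1 - mirna_fraction) of the final library, i.e. round(assigned x
    (1 - f)/f) reads per sample, so the realized miRNA-mapped fraction is
    ``mirna_fraction`` up to integer rounding.  Read order is shuffled.
    """
    if not config.adapter_seq:
        raise ValueError("adapter_seq must be non-empty")
    seq_of = {r.feature_id: r.mature_seq.upper().replace("U", "T") for r in reference}
    missing = [f for f in counts.feature_ids if f not in seq_of]
    if missing:
        raise ValueError(f"count matrix features missing from reference: {missing[:3]}")
    rng = _rng(config, "reads")
    f = config.mirna_fraction
    out: dict[str, list[str]] = {}
    for sample_id in counts.sample_ids:
        col = counts.counts[sample_id]
        reads: list[str] = []
        for fid, c in col.items():
            c = int(round(c))
            if c:
                read = (seq_of[fid] + config.adapter_seq)[: config.read_length]
                reads.extend([read] * c)
        n_assigned = len(reads)
        n_contam = int(round(n_assigned * (1 - f) / f))
        reads.extend(_decoy_reads(rng, n_contam, config.adapter_seq, config.read_length))
        rng.shuffle(reads)
        out[sample_id] = reads
    return out


def simulate_qpcr(
    truth: Mapping[str, float],
    config: SimulationConfig,
    normalizer_id: str = "snoR442",
    n_bio: int = 4,
    noise_sd: float = 0.1,
    baseline_ct: float = 25.0,
) -> pd.DataFrame:
    """Generate a Ct table under the inverse ddCt model.

    ``truth`` maps target_id -> signed fold change (knockdown vs control) and
    must include ``normalizer_id`` (with fold change 1, the definition of a
    normalizer).  For every well: Ct = baseline_ct - log2(relative
    expression) + N(0, noise_sd).  Each biological replicate carries 4
    technical measurements (2 cDNA preparations x 2 qPCR wells).
    """
    if normalizer_id not in truth:
        raise ValueError(f"truth must include the normalizer {normalizer_id!r}")
    if abs(_ratio_of(truth[normalizer_id]) - 1.0) > 1e-9:
        raise ValueError("normalizer must have fold change 1")
    rng = _rng(config, "qpcr")
    rows = []
    for target_id, signed_fc in truth.items():
        ratio = _ratio_of(signed_fc)
        for genotype, expr in (("control", 1.0), ("knockdown", ratio)):
            for bio in range(1, n_bio + 1):
                for cdna in (1, 2):
                    for well in (1, 2):
                        ct = baseline_ct - math.log2(expr) + rng.normal(0.0, noise_sd)
                        rows.append(
                            {
                                "target_id": target_id,
                                "normalizer_id": normalizer_id,
                                "genotype": genotype,
                                "bio_replicate": bio,
                                "tech_replicate": f"cdna{cdna}_well{well}",
                                "ct": ct,
                            }
                        )
    table = pd.DataFrame(rows)
    if (table["ct"] <= 0).any():
        raise ValueError("simulated Ct <= 0; raise baseline_ct")
    return table


def _ratio_of(signed_fc: float) -> float:
    if abs(signed_fc) < 1:
        raise ValueError("fold changes must use the signed convention (|fc| >= 1)")
    return signed_fc if signed_fc >= 1 else -1.0 / signed_fc


# ---------------------------------------------------------------------------
# File output


def write_fastq(reads: Iterable[str], path: str | Path, sample_id: str = "sample") -> None:
    """Write reads as FASTQ with constant maximal quality (quality is unused downstream)."""
    records = (
        SeqRecord(
            Seq(seq),
            id=f"{sample_id}_read{i}",
            description="",
            letter_annotations={"phred_quality": [40] * len(seq)},
        )
        for i, seq in enumerate(reads, start=1)
    )
    SeqIO.write(records, str(path), "fastq")


def write_reference_fasta(
    reference: Sequence[MiRNARecord], mature_path: str | Path, precursor_path: str | Path
) -> None:
    mature = [
        SeqRecord(Seq(r.mature_seq), id=r.feature_id, description=f"arm={r.arm}")
        for r in reference
    ]
    precursor = [
        SeqRecord(Seq(r.precursor_seq), id=r.feature_id, description="precursor")
        for r in reference
    ]
    SeqIO.write(mature, str(mature_path), "fasta")
    SeqIO.write(precursor, str(precursor_path), "fasta")


def load_reference_fasta(mature_path: str | Path, precursor_path: str | Path) -> list[MiRNARecord]:
    """Rebuild MiRNARecords from paired mature/precursor FASTA files."""
    precursors = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(precursor_path), "fasta")}
    records = []
    for rec in SeqIO.parse(str(mature_path), "fasta"):
        arm = "5p"
        for token in rec.description.split():
            if token.startswith("arm="):
                arm = token[4:]
        if rec.id not in precursors:
            raise ValueError(f"no precursor sequence for {rec.id}")
        records.append(
            MiRNARecord(
                feature_id=rec.id,
                mature_seq=str(rec.seq),
                precursor_seq=precursors[rec.id],
                arm=arm,
            )
        )
    return records
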