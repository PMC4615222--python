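"""End-to-end orchestration: simulate -> quantify -> detect -> filter ->
categorize -> classify -> report.

One configured run produces the full paper-style analysis of a synthetic
knockdown experiment: the detected-feature universe, the two concordance
filters, candidate selection against every parental replicate, the
three-way category summary with percentages, and a mature-vs-precursor
mechanism call for every candidate.  Stage boundaries are logged with record
counts so filter attrition is auditable, and the whole run is a
deterministic function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import filters as flt
from . import mechanism as mech
from . import quantify as qt
from . import simulate as sim

__all__ = ["RunConfig", "run", "load_run_config"]

logger = logging.getLogger("mirkd.pipeline")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``from_reads=True`` routes the simulation through FASTQ generation and
    the read-level quantifier (slow at full library sizes; intended for
    reduced depths), otherwise the simulated count matrix is used directly.
    """

    simulation: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    filters: flt.PipelineConfig = field(default_factory=flt.PipelineConfig)
    normalization_mode: str = "per_million_assigned"
    from_reads: bool = False
    spike_study_effects: bool = False  # replace effects with the 11-up/6-down study-like set
    outdir: Path | None = None


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a flat YAML file.

    Top-level keys ``simulation:`` and ``filters:`` hold the respective
    dataclass fields; remaining keys map onto RunConfig itself.
    """
    with open(path) as fh:
        raw: dict[str, Any] = yaml.safe_load(fh) or {}
    sim_kwargs = raw.pop("simulation", {}) or {}
    effects = [sim.Effect(**e) for e in sim_kwargs.pop("effects", [])]
    filt_kwargs = raw.pop("filters", {}) or {}
    if "whitelist" in filt_kwargs:
        filt_kwargs["whitelist"] = frozenset(filt_kwargs["whitelist"])
    if "library_size_range" in sim_kwargs:
        sim_kwargs["library_size_range"] = tuple(sim_kwargs["library_size_range"])
    outdir = raw.pop("outdir", None)
    return RunConfig(
        simulation=sim.SimulationConfig(effects=tuple(effects), **sim_kwargs),
        filters=flt.PipelineConfig(**filt_kwargs),
        outdir=Path(outdir) if outdir else None,
        **raw,
    )


def _ttest_feature(
    values: pd.DataFrame, feature: str, kd_samples: list[str], ctrl_samples: list[str]
) -> float:
    a = values.loc[feature, kd_samples].to_numpy(dtype=float)
    b = values.loc[feature, ctrl_samples].to_numpy(dtype=float)
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b).pvalue)


def _mechanism_evidence(
    mature_expr: qt.ExpressionTable,
    precursor_expr: qt.ExpressionTable,
    features: list[str],
    config: flt.PipelineConfig,
) -> pd.DataFrame:
    design = mature_expr.design
    kd = list(design.loc[design["genotype"] == "knockdown", "sample_id"])
    ctrl = list(design.loc[design["genotype"] != "knockdown", "sample_id"])
    rows = []
    for f in features:
        m_fc = flt.signed_fold_change(
            float(mature_expr.values.loc[f, kd].mean()),
            float(mature_expr.values.loc[f, ctrl].mean()),
            config.pseudocount,
        )
        p_fc = flt.signed_fold_change(
            float(precursor_expr.values.loc[f, kd].mean()),
            float(precursor_expr.values.loc[f, ctrl].mean()),
            config.pseudocount,
        )
        rows.append(
            {
                "feature_id": f,
                "mature_fc": m_fc,
                "mature_significant": _ttest_feature(mature_expr.values, f, kd, ctrl)
                < config.alpha,
                "precursor_fc": p_fc,
                "precursor_significant": _ttest_feature(precursor_expr.values, f, kd, ctrl)
                < config.alpha,
            }
        )
    return pd.DataFrame(rows)


def run(config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline and return the run report.

    When ``config.outdir`` is set, intermediate TSVs (reference, counts,
    expression, ground truth, per-feature results) and the JSON report are
    written there under fixed filenames.
    """
    sc = config.simulation
    logger.info("generating reference: %d features (seed %d)", sc.n_features, sc.seed)
    reference = sim.generate_reference(sc)
    if config.spike_study_effects:
        sc = dataclasses.replace(sc, effects=sim.study_effects(reference, sc))
    mature_counts, precursor_counts, truth, design = sim.simulate_experiment(reference, sc)

    if config.from_reads:
        logger.info("expanding counts into reads and re-quantifying")
        reads = sim.simulate_reads(reference, mature_counts, sc)
        mature_counts = qt.quantify_fastq(reads, reference, sc.adapter_seq, design=design)

    expr = qt.normalize_per_million(mature_counts, config.normalization_mode)
    precursor_expr = qt.normalize_per_million(precursor_counts, "per_million_assigned")

    detected = qt.detect(mature_counts)
    logger.info("detected %d/%d features (>1 read in all samples)", len(detected), sc.n_features)
    det_expr = qt.ExpressionTable(
        expr.values.loc[detected], design, expr.normalization_mode
    )

    parental = flt.parental_concordance(det_expr, config.filters)
    after_parental = [f for f in detected if f in parental.retained]
    logger.info("parental concordance: %d retained, %d excluded", len(after_parental), len(parental.excluded))

    rep_expr = qt.ExpressionTable(expr.values.loc[after_parental], design, expr.normalization_mode)
    replicate = flt.replicate_concordance(rep_expr, config.filters)
    retained = [f for f in after_parental if f in replicate.retained]
    logger.info("replicate concordance: %d retained, %d excluded", len(retained), len(replicate.excluded))

    ret_expr = qt.ExpressionTable(expr.values.loc[retained], design, expr.normalization_mode)
    selection = flt.candidate_selection(ret_expr, config.filters)
    candidates = list(selection.index[selection["candidate"]])
    logger.info("candidate selection: %d candidates", len(candidates))

    summary = flt.categorize_all(selection["grouped_fc"], config.filters)
    whitelisted = parental.whitelisted | replicate.whitelisted
    records = flt.build_records(
        selection,
        config.filters,
        passed_filters={
            f: {
                "detected": True,
                "parental_concordance": f in parental.retained,
                "replicate_concordance": f in replicate.retained,
                "candidate": f in candidates,
            }
            for f in retained
        },
        whitelisted=whitelisted,
    )

    evidence = _mechanism_evidence(det_expr, precursor_expr, candidates, config.filters)
    if len(evidence):
        calls, call_summary = mech.classify_table(evidence, config.filters)
    else:
        calls = pd.DataFrame(columns=list(mech.EVIDENCE_COLUMNS) + ["call", "discordant"])
        call_summary = {cls: 0 for cls in mech.MECHANISM_CLASSES}

    report: dict[str, Any] = {
        "seed": sc.seed,
        "config": {
            "simulation": _jsonable(dataclasses.asdict(sc)),
            "filters": _jsonable(dataclasses.asdict(config.filters)),
            "normalization_mode": config.normalization_mode,
            "from_reads": config.from_reads,
        },
        "stage_counts": {
            "features": sc.n_features,
            "detected": len(detected),
            "after_parental_concordance": len(after_parental),
            "after_replicate_concordance": len(retained),
            "candidates": len(candidates),
        },
        "category_summary": {
            "n": summary.n_total,
            "counts": dict(summary.counts),
            "percentages": dict(summary.percentages),
        },
        "candidates": candidates,
        "whitelisted": sorted(whitelisted),
        "mechanism_summary": call_summary,
        "versions": {"mirkd": _version()},
    }

    if config.outdir is not None:
        _write_outputs(
            config.outdir, reference, mature_counts, precursor_counts, truth, design,
            expr, selection, records, calls, report,
        )
    return report


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("mirkd")
    except PackageNotFoundError:
        return "unknown"


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_outputs(
    outdir, reference, mature_counts, precursor_counts, truth, design,
    expr, selection, records, calls, report,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim.write_reference_fasta(reference, outdir / "mature.fasta", outdir / "precursor.fasta")
    mature_counts.to_tsv(outdir / "mature_counts.tsv")
    precursor_counts.to_tsv(outdir / "precursor_counts.tsv")
    truth.to_csv(outdir / "ground_truth.tsv", sep="\t")
    design.to_csv(outdir / "design.tsv", sep="\t", index=False)
    expr.to_tsv(outdir / "expression.tsv")
    results = selection.copy()
    results["category"] = [r.category for r in records]
    results["whitelisted"] = [r.whitelisted for r in records]
    results.index.name = "feature_id"
    results.to_csv(outdir / "results.tsv", sep="\t")
    calls.to_csv(outdir / "mechanism_calls.tsv", sep="\t", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
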