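import dataclasses

import pytest

import mirkd
from mirkd import filters as flt
from mirkd import quantify as qt
from mirkd import simulate as sim


def run_filter_cascade(seed: int, dispersion: float = 0.01):
    """Simulate a spiked experiment and push it through the full cascade.

    Returns a dict with the intermediate artifacts used across tests:
    truth table, detected set, retained set, candidate-selection table and
    category summary.
    """
    config = sim.SimulationConfig(seed=seed, dispersion=dispersion)
    reference = sim.generate_reference(config)
    config = dataclasses.replace(config, effects=sim.study_effects(reference, config))
    mature, precursor, truth, design = sim.simulate_experiment(reference, config)
    expr = qt.normalize_per_million(mature)
    pipe = flt.PipelineConfig()

    detected = qt.detect(mature)
    det = qt.ExpressionTable(expr.values.loc[detected], design)
    parental = flt.parental_concordance(det, pipe)
    keep = [f for f in detected if f in parental.retained]
    replicate = flt.replicate_concordance(
        qt.ExpressionTable(expr.values.loc[keep], design), pipe
    )
    retained = [f for f in keep if f in replicate.retained]
    selection = flt.candidate_selection(
        qt.ExpressionTable(expr.values.loc[retained], design), pipe
    )
    summary = flt.categorize_all(selection["grouped_fc"], pipe)
    return {
        "config": config,
        "reference": reference,
        "mature": mature,
        "precursor": precursor,
        "truth": truth,
        "design": design,
        "expr": expr,
        "detected": detected,
        "retained": retained,
        "selection": selection,
        "summary": summary,
    }


@pytest.fixture(scope="session")
def cascade_seed1():
    return run_filter_cascade(seed=1)


@pytest.fixture(scope="session")
def small_experiment():
    """A low-depth experiment whose reads are cheap to expand and re-count."""
    config = sim.SimulationConfig(seed=11, library_size_range=(2e4, 2e4), dispersion=0.01)
    reference = sim.generate_reference(config)
    mature, precursor, truth, design = sim.simulate_experiment(reference, config)
    return config, reference, mature, design
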