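import numpy as np
import pandas as pd
import pytest

from sloppyspikes.analysis import AnalysisParams, run_analysis
from sloppyspikes.spike_io import SpikeDataset
from sloppyspikes.synth import GeneratorConfig, generate

# problem sizes for the end-to-end runs: a 33-min recording (NE = 20 epochs)
# with 8 ensembles keeps the suite fast while giving the epoch-level
# statistics (especially pairwise-correlation series) enough support
PIPELINE_SEEDS = (1, 2)
PIPELINE_DURATION_S = 2000.0
PIPELINE_Q = 8


@pytest.fixture(scope="session")
def pipeline_results():
    """Full analysis of generator-default recordings at two seeds."""
    out = {}
    for seed in PIPELINE_SEEDS:
        ds, truth = generate(GeneratorConfig(duration_s=PIPELINE_DURATION_S), seed=seed)
        res = run_analysis(ds, AnalysisParams(q_ensembles=PIPELINE_Q), seed=seed)
        out[seed] = {"dataset": ds, "truth": truth, "result": res}
    return out


def make_dataset(spikes, events=(), duration=10.0, classes=None, units=None):
    """Small helper to build a SpikeDataset from (unit, time) tuples."""
    if units is None:
        units = sorted({u for u, _ in spikes}) or [0]
    classes = classes or {}
    units_df = pd.DataFrame(
        {"unit_id": units, "cls": [classes.get(u, "single") for u in units]}
    )
    spikes_df = pd.DataFrame(
        {"unit_id": [u for u, _ in spikes], "time_s": [t for _, t in spikes]}
    )
    return SpikeDataset(
        units=units_df,
        spikes=spikes_df,
        events=np.asarray(events, dtype=float),
        duration=duration,
    )


@pytest.fixture
def toy_dataset():
    return make_dataset(
        [(1, 0.005), (1, 0.012), (2, 0.011)], events=[2.5, 5.0], duration=10.0
    )
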