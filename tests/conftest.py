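import numpy as np
import pandas as pd
import pytest

from ncflow import Experiment, ProbeClass
from ncflow.synthdata import SimConfig, null_experiment, reference_cohort, simulate_experiment


def make_experiment(counts: dict, classes: dict, groups=None, spike_fm=None,
                    lane=None) -> Experiment:
    """Build a small experiment from plain dicts (probe -> per-sample counts)."""
    counts_df = pd.DataFrame(counts).T
    counts_df.index.name = "probe"
    n = counts_df.shape[1]
    counts_df.columns = [f"S{i + 1}" for i in range(n)]
    probes = pd.DataFrame(
        {
            "probe_class": [classes[p].value for p in counts_df.index],
            "accession": "TEST",
            "spike_fm": [
                (spike_fm or {}).get(p, np.nan) for p in counts_df.index
            ],
        },
        index=counts_df.index,
    )
    samples = pd.DataFrame(
        {
            "group": groups or ["A"] * n,
            "cartridge": "C1",
        },
        index=pd.Index(counts_df.columns, name="sample_id"),
    )
    if lane:
        for key, values in lane.items():
            samples[key] = values
    return Experiment(counts=counts_df.astype(np.int64), probes=probes,
                      samples=samples)


@pytest.fixture
def tiny_experiment() -> Experiment:
    """4 samples; endogenous + bio-positive + HK + spikes, hand-set counts."""
    classes = {
        "GENE1": ProbeClass.ENDOGENOUS,
        "GENE2": ProbeClass.ENDOGENOUS,
        "TFF1": ProbeClass.BIO_POSITIVE,
        "MUC2": ProbeClass.BIO_POSITIVE,
        "GAPDH": ProbeClass.HOUSEKEEPING,
        "ACTB": ProbeClass.HOUSEKEEPING,
        "POS_A(128)": ProbeClass.POSITIVE_SPIKE,
        "POS_E(0.5)": ProbeClass.POSITIVE_SPIKE,
        "NEG_A": ProbeClass.NEGATIVE_SPIKE,
        "NEG_B": ProbeClass.NEGATIVE_SPIKE,
        "NEG_C": ProbeClass.NEGATIVE_SPIKE,
    }
    counts = {
        "GENE1": [120, 100, 90, 140],
        "GENE2": [40, 55, 60, 45],
        "TFF1": [200, 210, 190, 205],
        "MUC2": [80, 75, 90, 85],
        "GAPDH": [500, 480, 510, 495],
        "ACTB": [300, 310, 290, 305],
        "POS_A(128)": [20000, 19500, 20500, 19800],
        "POS_E(0.5)": [90, 85, 95, 88],
        "NEG_A": [10, 8, 12, 9],
        "NEG_B": [14, 12, 10, 11],
        "NEG_C": [6, 10, 8, 10],
    }
    spikes = {"POS_A(128)": 128.0, "POS_E(0.5)": 0.5}
    return make_experiment(counts, classes, groups=["TA", "TA", "SSL", "SSL"],
                           spike_fm=spikes)


@pytest.fixture(scope="session")
def default_sim():
    return simulate_experiment(SimConfig(seed=11))


@pytest.fixture(scope="session")
def null_cohort_87():
    """Exchangeable-null cohort at the retained-cohort size (21/24/42)."""
    cfg = SimConfig(group_sizes=(("SSL", 21), ("TV", 24), ("TA", 42)), seed=2025)
    return null_experiment(cfg)


@pytest.fixture(scope="session")
def study_cohort():
    return reference_cohort(seed=0)
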