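import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mirnet as mn

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg() -> mn.SimConfig:
    """A small but non-trivial study: planted DE in both mutants, decoy dbs."""
    return mn.SimConfig(
        n_genes=400, n_mirnas=80, n_per_group=6, frac_de=0.15, lfc_magnitude=2.5, seed=42
    )


@pytest.fixture(scope="session")
def small_experiment(small_cfg):
    """Linked mRNA/miRNA matrices with planted target pairs (seeded)."""
    from dataclasses import replace

    mrna_cm, mirna_cm, truth = mn.simulate_experiment(
        small_cfg, replace(small_cfg, n_per_group=5), n_true_pairs=30
    )
    return mrna_cm, mirna_cm, truth


@pytest.fixture()
def tiny_counts() -> mn.CountMatrix:
    """Deterministic 4-feature, 4-sample matrix for hand-checkable math."""
    counts = pd.DataFrame(
        {
            "s1": [10, 100, 0, 40],
            "s2": [12, 90, 0, 38],
            "s3": [11, 110, 0, 42],
            "s4": [9, 95, 0, 41],
        },
        index=["f1", "f2", "f3", "f4"],
    )
    meta = pd.DataFrame(
        {
            "genotype": ["WT", "WT", "KO", "KO"],
            "assay": "mRNA",
            "batch": "batch1",
        },
        index=counts.columns,
    )
    return mn.CountMatrix(counts, meta)
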