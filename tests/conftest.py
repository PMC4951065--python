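import warnings

import numpy as np
import pandas as pd
import pytest

from dielomix.synthdata import SimulationConfig, simulate_study

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_bundle():
    """A small simulated study shared across tests (read-only)."""
    return simulate_study(SimulationConfig(n_genes=120, seed=7))


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Zero-noise, delay-0-only study: protein tracks mRNA exactly."""
    cfg = SimulationConfig(
        n_genes=40,
        seed=3,
        delay_class_probs={"delay0": 1.0},
        hptr_fraction=0.0,
        feature_effect_sizes={},
        noise_sd_mrna=0.0,
        noise_sd_protein=0.0,
        noise_sd_peptide=0.0,
        missing_rate=0.0,
        utr_missing_rate=0.0,
    )
    return simulate_study(cfg)


@pytest.fixture()
def toy_peptide_table():
    """Hand-built 10-peptide table over 2 time points x 2 bioreps x 3 techreps.

    Designed so presence/absence and the coverage filter can be verified by
    hand: proteins A (2 well-covered unique peptides), B (one peptide sparse),
    C (single peptide only), D (covered by one unique + one shared peptide).
    """
    from dielomix.datatypes import PeptideTable

    datasets = []
    for tp in ("T1", "T2"):
        for b in (1, 2):
            for t in (1, 2, 3):
                datasets.append((f"ds_{tp}_b{b}_t{t}", tp, b, t))
    ds = pd.DataFrame(
        datasets, columns=["dataset_id", "timepoint", "biorep", "techrep"]
    ).set_index("dataset_id")
    n = len(ds)  # 12 datasets
    rng = np.random.default_rng(0)

    def row(present_mask, level):
        vals = np.full(n, np.nan)
        vals[present_mask] = level + rng.normal(0, 0.01, int(np.sum(present_mask)))
        return vals

    full = np.ones(n, dtype=bool)
    half = np.zeros(n, dtype=bool)
    half[:6] = True  # all of T1 only
    sparse = np.zeros(n, dtype=bool)
    sparse[:3] = True  # 3 of 12 datasets
    rows = {
        "A_p1": (row(full, 5.0), ("A",)),
        "A_p2": (row(full, 4.5), ("A",)),
        "B_p1": (row(sparse, 6.0), ("B",)),
        "B_p2": (row(full, 6.2), ("B",)),
        "C_p1": (row(full, 3.0), ("C",)),
        "D_p1": (row(full, 7.0), ("D",)),
        "D_p2": (row(full, 7.1), ("D", "A")),
        "E_p1": (row(half, 5.5), ("E",)),
        "E_p2": (row(half, 5.6), ("E",)),
        "E_p3": (row(sparse, 5.4), ("E",)),
    }
    abundance = pd.DataFrame(
        {pid: vals for pid, (vals, _) in rows.items()}, index=ds.index
    ).T
    mapping = pd.DataFrame(
        {
            "protein_ids": [prots for _, prots in rows.values()],
            "unique": [len(prots) == 1 for _, prots in rows.values()],
        },
        index=pd.Index(rows.keys(), name="peptide_id"),
    )
    return PeptideTable(abundance, mapping, ds)
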