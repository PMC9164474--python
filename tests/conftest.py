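import numpy as np
import pandas as pd
import pytest

from kinbayes import (
    ActivityAnnotation,
    EvidenceBundle,
    KinaseRegistry,
    PhosphoSite,
    SequenceWindow,
)
from kinbayes.io import timecourse_from_replicates


def make_site(site_id, window, means, gene=None, n_rep=3):
    """A PhosphoSite with exact per-time means (replicates all equal)."""
    reps = np.repeat(np.asarray(means, dtype=float)[:, None], n_rep, axis=1)
    return PhosphoSite(
        site_id=site_id,
        gene_symbol=gene or f"G_{site_id}",
        residue=window[6],
        position=10,
        window=SequenceWindow(window),
        timecourse=timecourse_from_replicates(reps),
    )


def small_registry(n=3):
    names = tuple(f"K{i + 1}" for i in range(n))
    neighbors = (
        {k: names[(i + 1) % n] for i, k in enumerate(names)} if n > 1 else {}
    )
    return KinaseRegistry(names, {k: "AGC" for k in names}, neighbors)


def uniform_bundle(registry, n_fractions=3):
    """Evidence identical across kinases: every step's likelihood is constant."""
    kinases = list(registry.kinases)
    ones = pd.Series(1.0, index=kinases)
    fractions = [f"frac{i}" for i in range(n_fractions)]
    profile = np.full(n_fractions, 1.0 / n_fractions)
    positions = list(range(-6, 7))
    freqs = pd.DataFrame(1.0 / 20, index=positions, columns=list("ACDEFGHIKLMNPQRSTVWY"))
    return EvidenceBundle(
        transcript=ones,
        protein_a=ones,
        protein_b=ones,
        sty=pd.DataFrame(
            {"f_S": 1.0, "f_T": 0.0, "f_Y": 0.0}, index=kinases
        ),
        kinase_profiles=pd.DataFrame([profile] * len(kinases), index=kinases,
                                     columns=fractions),
        substrate_profiles=pd.DataFrame([profile], index=["G_s1"],
                                        columns=fractions),
        activity=ActivityAnnotation({}),
        kinase_motifs={k: freqs for k in kinases},
        background=pd.Series(1.0 / 20, index=list("ACDEFGHIKLMNPQRSTVWY")),
        pivots={"transcript": 1.0, "protein_a": 1.0, "protein_b": 1.0,
                "colocalization": 1.0, "motif": 1.0},
        neighbor_map=dict(registry.neighbor_map),
    )


@pytest.fixture(scope="session")
def default_experiment():
    """One default synthetic experiment, shared across tests."""
    from kinbayes import SimulationConfig, simulate_experiment

    return simulate_experiment(SimulationConfig(seed=7))


@pytest.fixture
def toy_registry():
    return small_registry(3)
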