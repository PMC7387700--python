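import numpy as np
import pytest

from phlastab import (
    PlantedDatasetSpec,
    ToySpec,
    assemble_matrix,
    build_labels,
    build_toy_structure,
    generate_planted_dataset,
    train_model,
)


@pytest.fixture(scope="session")
def small_planted():
    """A compact planted-signal dataset: 2 alleles, geometric R-D signal."""
    spec = PlantedDatasetSpec(
        alleles=("HLA-A*01:01", "HLA-A*02:01"),
        n_positives=14,
        n_negatives=6,
        mean_conformations=4,
        seed=11,
    )
    return spec, generate_planted_dataset(spec)


@pytest.fixture(scope="session")
def small_matrix(small_planted):
    _, data = small_planted
    labels = build_labels(data.positives, data.negatives)
    return assemble_matrix(labels, data.store, mode="ensemble")


@pytest.fixture(scope="session")
def small_forest(small_matrix):
    """A 100-tree forest on the small planted matrix (bootstrap on)."""
    return train_model(small_matrix, "rf", seed=0, n_estimators=100)


@pytest.fixture(scope="session")
def exact_forest(small_matrix):
    """Forest with bootstrapping disabled: bias identities are exact."""
    return train_model(small_matrix, "rf", seed=0, n_estimators=60, bootstrap=False)


@pytest.fixture()
def toy_pair_record():
    """One-residue peptide vs two HLA residues at known distances."""
    spec = ToySpec(
        peptide="R", hla="DD", contacts={(1, 1): 2.0, (1, 2): 4.0},
        allele="HLA-A*01:01",
    )
    return build_toy_structure(spec)[0]


def random_toy_record(rng: np.random.Generator, n_pep: int = None, n_hla: int = None):
    """A random small structure with random feasible contact targets."""
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    n_pep = n_pep or int(rng.integers(1, 6))
    n_hla = n_hla or int(rng.integers(1, 6))
    peptide = "".join(rng.choice(aas, n_pep))
    hla = "".join(rng.choice(aas, n_hla))
    contacts = {}
    for h in range(1, n_hla + 1):
        if rng.random() < 0.7:
            p = int(rng.integers(1, n_pep + 1))
            contacts[(p, h)] = float(rng.uniform(2.0, 8.0))
    spec = ToySpec(
        peptide=peptide, hla=hla, contacts=contacts,
        seed=int(rng.integers(2**31 - 1)),
    )
    return build_toy_structure(spec)[0]
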