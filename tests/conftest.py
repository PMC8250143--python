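import numpy as np
import pandas as pd
import pytest

from gsblup import (
    MarkerMatrix,
    Pedigree,
    RandomTermSpec,
    RelationshipMatrix,
    compute_A,
    compute_G,
)
from gsblup.simdata import SimConfig, simulate_markers, simulate_phenotypes


def random_psd(n: int, rng: np.random.Generator, unit_diag: bool = False):
    """Well-conditioned random PSD matrix (Wishart-style)."""
    B = rng.standard_normal((n, 2 * n)) / np.sqrt(2 * n)
    K = B @ B.T
    if unit_diag:
        d = np.sqrt(np.diag(K))
        K = K / np.outer(d, d)
    return K


def labelled_psd(n, rng, prefix="g", unit_diag=False, kind="user"):
    return RelationshipMatrix(
        random_psd(n, rng, unit_diag), [f"{prefix}{i + 1}" for i in range(n)], kind=kind
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_pedigree():
    """Founders, a cross, a selfed offspring."""
    return Pedigree(
        [
            ("F1", None, None),
            ("F2", None, None),
            ("O", "F1", "F2"),
            ("S", "O", "O"),
        ]
    )


@pytest.fixture
def fullsib_pedigree():
    """Three generations of full-sib mating, 8 individuals."""
    return Pedigree(
        [
            ("F1", None, None),
            ("F2", None, None),
            ("A1", "F1", "F2"),
            ("A2", "F1", "F2"),
            ("B1", "A1", "A2"),
            ("B2", "A1", "A2"),
            ("C1", "B1", "B2"),
            ("C2", "B1", "B2"),
        ]
    )


@pytest.fixture
def grouped_dataset(rng):
    """Replicated one-term dataset with a correlated K: 30 genotypes x 3 reps."""
    g = 30
    K = labelled_psd(g, rng, unit_diag=True)
    Z = np.kron(np.eye(g), np.ones((3, 1)))
    data, true_u, _ = simulate_phenotypes(
        [(Z, K, 0.5)], 0.2, seed=11, term_names=["GID"]
    )
    return data, K, true_u


def simulate_two_term(n, seed, sigma2=(0.25, 0.20), sigma_e2=0.05, m_markers=400):
    """Marker-GRM + pedigree-A two-term dataset with one record per line."""
    cfg = SimConfig(
        n_individuals=n,
        m_markers=m_markers,
        founders=max(6, n // 12),
        generations=3,
        offspring_per_generation=n,  # unused sizes trimmed below
        seed=seed,
    )
    markers = simulate_markers(cfg)
    G = compute_G(markers)
    # pedigree over the same ids: founders unknown, then chained matings
    rng_ = np.random.default_rng(seed + 1)
    ids = markers.row_labels
    nf = max(4, n // 10)
    records = [(ids[i], None, None) for i in range(nf)]
    for i in range(nf, n):
        p1, p2 = rng_.choice(i, size=2, replace=False)
        records.append((ids[i], ids[p1], ids[p2]))
    A = compute_A(Pedigree(records))
    A = A.subset(ids)
    Z = np.eye(n)
    data, true_u, _ = simulate_phenotypes(
        [(Z, G, sigma2[0]), (Z, A, sigma2[1])],
        sigma_e2,
        seed=seed + 2,
        term_names=["markers", "pedigree"],
    )
    # both terms group by the same genotype id column
    data["GID"] = data["markers"]
    data = data[["GID", "y"]]
    terms = [
        RandomTermSpec("markers", "GID", G),
        RandomTermSpec("pedigree", "GID", A),
    ]
    return data, terms, true_u


@pytest.fixture
def two_term_dataset():
    return simulate_two_term(n=120, seed=5)
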