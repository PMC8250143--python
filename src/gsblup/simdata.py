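"""Synthetic genomic-selection fixtures: marker panels, pedigrees, hybrid
designs, and phenotypes drawn from the generative mixed model

    y = X beta + sum_j Z_j u_j + e,   u_j ~ N(0, sigma_j^2 K_j),  e ~ N(0, sigma_e^2 I)

with known variance components, so estimation and prediction can be tested
against ground truth.  All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .relmat import (
    MarkerMatrix,
    Pedigree,
    RelationshipMatrix,
    factorize,
    kron_kernel,
)

__all__ = [
    "SimConfig",
    "simulate_markers",
    "simulate_pedigree",
    "simulate_phenotypes",
    "make_hybrid_fixture",
]


@dataclass
class SimConfig:
    """Configuration for the synthetic generators.

    Defaults mirror a wheat-style genomic-selection study: a few hundred
    lines genotyped with ~1e3 dominant 0/1 markers, intermediate allele
    frequencies, and variance components of roughly (0.22, 0.21) genetic vs
    0.035 residual on the phenotypic scale of a standardized yield trait.
    """

    n_individuals: int = 100
    m_markers: int = 500
    coding: str = "0/1"  # "0/1" (dominant) or "0/1/2" (dosage)
    maf_range: tuple[float, float] = (0.05, 0.5)
    founders: int = 10
    generations: int = 3
    offspring_per_generation: int = 20
    variances: tuple[float, ...] = (0.22, 0.21)
    residual_variance: float = 0.035
    intercept: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.coding not in {"0/1", "0/1/2"}:
            raise ValueError("coding must be '0/1' or '0/1/2'")
        if any(v < 0 for v in self.variances) or self.residual_variance < 0:
            raise ValueError("variances must be nonnegative")


def simulate_markers(config: SimConfig) -> MarkerMatrix:
    """Independent biallelic markers with allele frequency uniform in maf_range.

    "0/1" draws Bernoulli(q) presence/absence codes (DArT-style dominant
    markers); "0/1/2" draws Binomial(2, q) allele dosages.  No linkage
    disequilibrium is simulated.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.m_markers
    q = rng.uniform(*config.maf_range, size=m)
    if config.coding == "0/1":
        X = (rng.random((n, m)) < q).astype(float)
    else:
        X = rng.binomial(2, q, size=(n, m)).astype(float)
    labels = [f"L{i + 1:04d}" for i in range(n)]
    return MarkerMatrix(X, labels, [f"M{k + 1}" for k in range(m)])


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Random-mating pedigree: founders, then generations of offspring whose
    two parents are drawn (without self-mating) from the previous generation."""
    if config.founders < 2:
        raise ValueError("need at least 2 founders")
    if config.generations < 1:
        raise ValueError("need at least 1 generation")
    rng = np.random.default_rng(config.seed)
    records: list[tuple[str, str | None, str | None]] = []
    prev = [f"F{i + 1}" for i in range(config.founders)]
    for fid in prev:
        records.append((fid, None, None))
    for g in range(1, config.generations + 1):
        cur = []
        for j in range(config.offspring_per_generation):
            p1, p2 = rng.choice(len(prev), size=2, replace=False)
            child = f"G{g}_{j + 1}"
            records.append((child, prev[p1], prev[p2]))
            cur.append(child)
        prev = cur
    return Pedigree(records)


def simulate_phenotypes(
    terms: list[tuple[np.ndarray, RelationshipMatrix, float]],
    sigma_e2: float,
    seed: int,
    X: np.ndarray | None = None,
    beta: np.ndarray | None = None,
    factor_labels: list[np.ndarray] | None = None,
    term_names: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.Series], np.ndarray]:
    """Draw phenotypes from the generative mixed model.

    ``terms`` is a list of (Z incidence n x r_j, K_j over the r_j levels,
    sigma_j^2).  Each u_j = sigma_j L_j z_j with z_j iid standard normal and
    L_j L_j' = K_j, then y = X beta + sum Z_j u_j + e.  Returns the phenotype
    table (response column "y" plus one factor column per term), the true
    random effects per term, and the true beta.
    """
    if not terms:
        raise ValueError("at least one random term is required")
    rng = np.random.default_rng(seed)
    n = terms[0][0].shape[0]
    if X is None:
        X = np.ones((n, 1))
        beta = np.array([0.0]) if beta is None else np.asarray(beta, float)
    else:
        X = np.asarray(X, float)
        beta = np.zeros(X.shape[1]) if beta is None else np.asarray(beta, float)
    if term_names is None:
        term_names = [f"term{j + 1}" for j in range(len(terms))]
    y = X @ beta
    data = pd.DataFrame(index=range(n))
    true_u: dict[str, pd.Series] = {}
    for name, (Z, K, s2) in zip(term_names, terms):
        if Z.shape[0] != n:
            raise ValueError("all incidence matrices must have the same row count")
        L = factorize(K, "auto").factor
        z = rng.standard_normal(K.n)
        u = np.sqrt(s2) * (L @ z)
        y = y + Z @ u
        true_u[name] = pd.Series(u, index=pd.Index(K.labels, name="level"))
        level_of_row = np.asarray(K.labels, dtype=object)[np.argmax(Z, axis=1)]
        data[name] = level_of_row
    y = y + np.sqrt(sigma_e2) * rng.standard_normal(n)
    data["y"] = y
    return data, true_u, beta


def make_hybrid_fixture(
    n_parents1: int = 20,
    n_parents2: int = 20,
    n_phenotyped: int = 100,
    seed: int = 0,
    sigma2_gca1: float = 0.016,
    sigma2_gca2: float = 0.001,
    sigma2_sca: float = 0.002,
    sigma_e2: float = 0.001,
    n_locations: int = 4,
) -> tuple[pd.DataFrame, RelationshipMatrix, RelationshipMatrix]:
    """Factorial hybrid (combining-ability) fixture.

    Emulates a two-heterotic-group maize design: all n1 x n2 crosses are
    enumerated, a random subset is "phenotyped" in each of ``n_locations``
    locations, and the rest carry missing responses (to be predicted).  The
    response is built from GCA effects of each parent group (covariances K1,
    K2 drawn as marker-free exchangeable-plus-noise relationship matrices), an
    SCA effect with covariance K1 (x) K2, a fixed location effect, and iid
    residual.  Returns (phenotype table, K1, K2); the table has columns
    Location, GCA1, GCA2, SCA, y.
    """
    if n_phenotyped > n_parents1 * n_parents2:
        raise ValueError("n_phenotyped exceeds the number of possible crosses")
    rng = np.random.default_rng(seed)

    def _random_relmat(n: int, prefix: str) -> RelationshipMatrix:
        # PSD with unit-ish diagonal: scaled Wishart-style B B'/m
        B = rng.standard_normal((n, 3 * n)) / np.sqrt(3 * n)
        K = B @ B.T
        d = np.sqrt(np.diag(K))
        K = K / np.outer(d, d)
        return RelationshipMatrix(K, [f"{prefix}{i + 1}" for i in range(n)])

    K1 = _random_relmat(n_parents1, "P")
    K2 = _random_relmat(n_parents2, "M")
    K3 = kron_kernel(K1, K2)
    u1 = np.sqrt(sigma2_gca1) * (factorize(K1).factor @ rng.standard_normal(K1.n))
    u2 = np.sqrt(sigma2_gca2) * (factorize(K2).factor @ rng.standard_normal(K2.n))
    u3 = np.sqrt(sigma2_sca) * (factorize(K3).factor @ rng.standard_normal(K3.n))
    loc_eff = np.concatenate([[0.0], rng.normal(0, 0.05, size=n_locations - 1)])
    crosses = [(a, b) for a in range(K1.n) for b in range(K2.n)]
    phen_idx = set(rng.choice(len(crosses), size=n_phenotyped, replace=False).tolist())
    rows = []
    for loc in range(n_locations):
        for c, (a, b) in enumerate(crosses):
            hyb = f"{K1.labels[a]}:{K2.labels[b]}"
            if c in phen_idx:
                yv = (
                    loc_eff[loc]
                    + u1[a]
                    + u2[b]
                    + u3[c]
                    + np.sqrt(sigma_e2) * rng.standard_normal()
                )
            else:
                yv = np.nan
            rows.append(
                {
                    "Location": f"Loc{loc + 1}",
                    "GCA1": K1.labels[a],
                    "GCA2": K2.labels[b],
                    "SCA": hyb,
                    "y": yv,
                }
            )
    return pd.DataFrame(rows), K1, K2
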