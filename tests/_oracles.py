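"""Independent oracles used by the test suite.

These deliberately avoid the package's computational routes: the A-matrix
oracle is a Monte-Carlo allele-dropping simulation; the REML oracle assembles
the restricted likelihood densely on the original covariance scale with
explicit inverses; the conditional-mean oracle partitions the joint normal
with explicit matrix inversion.
"""

from __future__ import annotations

import numpy as np


def gene_drop_A(records, n_rep: int, seed: int) -> np.ndarray:
    """Estimate the additive relationship matrix by allele dropping.

    ``records`` are (progeny, parent1, parent2) in topological order with
    ``None`` for unknown parents.  Each founder slot receives a unique allele;
    progeny inherit one random allele per parent.  A_ij is estimated as the
    mean over replicates of half the count of identical-by-descent allele
    pairs between i and j (which equals 2 * kinship; the diagonal estimates
    1 + inbreeding).
    """
    rng = np.random.default_rng(seed)
    alleles: dict[str, np.ndarray] = {}
    next_allele = 0
    for prog, p1, p2 in records:
        al = np.empty((2, n_rep), dtype=np.int64)
        for slot, par in enumerate((p1, p2)):
            if par is None:
                al[slot] = next_allele
                next_allele += 1
            else:
                pick = rng.integers(0, 2, size=n_rep)
                al[slot] = alleles[par][pick, np.arange(n_rep)]
        alleles[prog] = al
    ids = [r[0] for r in records]
    n = len(ids)
    A = np.zeros((n, n))
    for i in range(n):
        ai = alleles[ids[i]]
        for j in range(i, n):
            bj = alleles[ids[j]]
            ibd = sum(
                (ai[s] == bj[t]).mean() for s in range(2) for t in range(2)
            )
            A[i, j] = A[j, i] = 0.5 * ibd
    return A


def reml_loglik_dense(y, X, Z_list, K_list, sigma2_list, sigma_e2) -> float:
    """Restricted log-likelihood assembled densely on the original scale.

    V = sum_j sigma_j^2 Z_j K_j Z_j' + sigma_e^2 I; beta_hat by GLS; then
    l_R = -1/2 [ (n-p) log 2pi + log|V| + log|X'V^-1 X| + r' V^-1 r ].
    Uses explicit inverses — independent of the package's profiled,
    transformed-scale route.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    V = sigma_e2 * np.eye(n)
    for Z, K, s2 in zip(Z_list, K_list, sigma2_list):
        V = V + s2 * (Z @ K @ Z.T)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    _, logdet_V = np.linalg.slogdet(V)
    _, logdet_XtViX = np.linalg.slogdet(XtViX)
    quad = float(r @ Vi @ r)
    return -0.5 * ((n - p) * np.log(2 * np.pi) + logdet_V + logdet_XtViX + quad)


def blup_dense(y, X, beta, Z_list, K_list, sigma2_list, sigma_e2):
    """Original-scale BLUPs u_j^ = sigma_j^2 K_j Z_j' V^-1 (y - X beta)."""
    n = len(y)
    V = sigma_e2 * np.eye(n)
    for Z, K, s2 in zip(Z_list, K_list, sigma2_list):
        V = V + s2 * (Z @ K @ Z.T)
    Vi_r = np.linalg.solve(V, np.asarray(y) - X @ beta)
    return [s2 * K @ Z.T @ Vi_r for Z, K, s2 in zip(Z_list, K_list, sigma2_list)]


def mvn_conditional_mean(K: np.ndarray, idx1, idx2, u1) -> np.ndarray:
    """E(u2 | u1 = u1) for u ~ N(0, K), by explicit partition and inversion."""
    idx1 = np.asarray(idx1)
    idx2 = np.asarray(idx2)
    K11 = K[np.ix_(idx1, idx1)]
    K21 = K[np.ix_(idx2, idx1)]
    return K21 @ np.linalg.inv(K11) @ np.asarray(u1)
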