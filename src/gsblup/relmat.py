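"""Relationship and kernel matrices for genomic prediction.

Builds the covariance structures that enter the mixed model as random-effect
covariances: the pedigree-based numerator relationship matrix A, the marker
genomic relationship matrix G = WW'/p, Gaussian/exponential kernels on scaled
marker distances, and Kronecker-product covariances for hybrid (combining
ability) models.  Also provides the Cholesky/eigen factorization used to
absorb a covariance into the random-effect design matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "MarkerMatrix",
    "RelationshipMatrix",
    "DistanceMatrix",
    "CovFactor",
    "compute_A",
    "compute_G",
    "scaled_distances",
    "gaussian_kernel",
    "exponential_kernel",
    "kron_kernel",
    "factorize",
]

#: eigenvalues more negative than -PSD_RTOL * lambda_max are a hard error;
#: anything in [-PSD_RTOL*lambda_max, 0] is clipped.
PSD_RTOL = 1e-8

UNKNOWN_PARENT_CODES = {"", "0", "NA", "na", "nan", None}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, duplicate progeny)."""


def _is_unknown(parent) -> bool:
    if parent is None:
        return True
    if isinstance(parent, float) and np.isnan(parent):
        return True
    return str(parent).strip() in UNKNOWN_PARENT_CODES


@dataclass
class Pedigree:
    """Ordered pedigree records (progeny, parent1, parent2).

    Unknown parents are encoded as ``None`` (accepted aliases on input:
    empty string, "0", "NA").  Validation enforces unique progeny ids and a
    cycle-free ancestry; :meth:`toposorted` returns a copy in which every
    parent precedes its progeny.
    """

    records: list[tuple[str, str | None, str | None]]

    def __post_init__(self):
        cleaned = []
        for prog, p1, p2 in self.records:
            cleaned.append(
                (
                    str(prog),
                    None if _is_unknown(p1) else str(p1),
                    None if _is_unknown(p2) else str(p2),
                )
            )
        self.records = cleaned
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PedigreeError(f"duplicate progeny id(s): {dup}")

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    def toposorted(self) -> "Pedigree":
        """Kahn's algorithm; parents appearing only as parents become founders."""
        known = set(self.ids)
        rec = dict()
        order_seen: list[str] = []
        for prog, p1, p2 in self.records:
            for p in (p1, p2):
                if p is not None and p not in known:
                    known.add(p)
                    rec[p] = (p, None, None)
                    order_seen.append(p)
            rec[prog] = (prog, p1, p2)
            order_seen.append(prog)
        children: dict[str, list[str]] = {i: [] for i in known}
        indeg = {i: 0 for i in known}
        for prog, p1, p2 in rec.values():
            for p in (p1, p2):
                if p is not None:
                    children[p].append(prog)
                    indeg[prog] += 1
        queue = [i for i in order_seen if indeg[i] == 0]
        out: list[tuple[str, str | None, str | None]] = []
        while queue:
            i = queue.pop(0)
            out.append(rec[i])
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(out) != len(known):
            on_cycle = sorted(i for i in known if indeg[i] > 0)
            raise PedigreeError(
                f"pedigree contains a cycle involving individual(s): {on_cycle[:5]}"
            )
        return Pedigree(out)


@dataclass
class MarkerMatrix:
    """Individuals x markers genotype codes (0/1 dominant or 0/1/2 dosage)."""

    values: np.ndarray
    row_labels: list[str]
    column_labels: list[str] = field(default_factory=list)
    max_missing_frac: float = 0.5

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("marker matrix must be 2-dimensional")
        n, m = self.values.shape
        if m < 1:
            raise ValueError("marker matrix needs at least one marker column")
        self.row_labels = [str(x) for x in self.row_labels]
        if len(self.row_labels) != n:
            raise ValueError("row_labels length does not match matrix")
        if len(set(self.row_labels)) != n:
            raise ValueError("duplicate genotype ids in marker matrix")
        if not self.column_labels:
            self.column_labels = [f"M{k + 1}" for k in range(m)]
        miss = np.isnan(self.values).mean(axis=0)
        if (miss > self.max_missing_frac).any():
            bad = [self.column_labels[k] for k in np.where(miss > self.max_missing_frac)[0]]
            raise ValueError(
                f"{len(bad)} marker column(s) exceed the missing-fraction limit "
                f"{self.max_missing_frac}: {bad[:5]}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def imputed(self) -> np.ndarray:
        """Column-mean imputation of missing cells (returns a copy)."""
        X = self.values.copy()
        if np.isnan(X).any():
            means = np.nanmean(X, axis=0)
            idx = np.where(np.isnan(X))
            X[idx] = means[idx[1]]
        return X


@dataclass
class RelationshipMatrix:
    """Labelled symmetric PSD covariance among genotype levels."""

    values: np.ndarray
    labels: list[str]
    kind: str = "user"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = [str(x) for x in self.labels]
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("covariance matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in relationship matrix")
        scale = np.abs(self.values).max() if n else 1.0
        if scale > 0 and np.abs(self.values - self.values.T).max() > 1e-10 * scale:
            raise ValueError("relationship matrix is not symmetric within tolerance")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, labels) -> np.ndarray:
        pos = {lab: i for i, lab in enumerate(self.labels)}
        missing = [str(x) for x in labels if str(x) not in pos]
        if missing:
            raise KeyError(
                f"{len(missing)} level(s) absent from covariance labels: {missing[:10]}"
            )
        return np.array([pos[str(x)] for x in labels], dtype=int)

    def subset(self, labels) -> "RelationshipMatrix":
        idx = self.index_of(labels)
        return RelationshipMatrix(
            self.values[np.ix_(idx, idx)], [str(x) for x in labels], kind=self.kind
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class DistanceMatrix:
    """Scaled Euclidean distances s_ij = d_ij / sqrt(m) between genotypes."""

    values: np.ndarray
    labels: list[str]
    scaling: str = "euclidean/sqrt(m)"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = [str(x) for x in self.labels]
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be nonnegative")
        if np.abs(np.diag(self.values)).max(initial=0.0) > 1e-10:
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = np.clip(0.5 * (self.values + self.values.T), 0.0, None)


@dataclass
class CovFactor:
    """Factor L with L @ L.T == K (after PSD clipping)."""

    factor: np.ndarray
    method: str
    labels: list[str]
    clip_report: dict = field(default_factory=dict)


def compute_A(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular (Henderson) recursion.

    Individuals are processed in topological order.  With parents s, d of
    individual i (already tabulated):

        A_ii = 1 + 0.5 * A_sd            (inbreeding from parental kinship)
        A_ij = 0.5 * (A_js + A_jd)       for each earlier j

    Unknown parents contribute 0, i.e. founders are unrelated and non-inbred.
    """
    ped = pedigree.toposorted()
    ids = ped.ids
    n = len(ids)
    pos = {g: i for i, g in enumerate(ids)}
    A = np.zeros((n, n))
    for prog, p1, p2 in ped.records:
        i = pos[prog]
        s = pos[p1] if p1 is not None else None
        d = pos[p2] if p2 is not None else None
        if s is not None and d is not None:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        for j in range(i):
            val = 0.0
            if s is not None:
                val += 0.5 * A[j, s]
            if d is not None:
                val += 0.5 * A[j, d]
            A[i, j] = A[j, i] = val
    return RelationshipMatrix(A, ids, kind="pedigree_A")


def compute_G(
    markers: MarkerMatrix, center: bool = True, standardize: bool = True
) -> RelationshipMatrix:
    """Genomic relationship matrix G = WW'/p from centered, standardized markers.

    Missing cells are imputed by the column mean first.  Zero-variance columns
    are dropped (with a warning) and p reduced accordingly; the sample (n-1)
    standard deviation is used for standardization.
    """
    X = markers.imputed()
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = int((~keep).sum())
        if not keep.any():
            raise ValueError("all marker columns have zero variance")
        warnings.warn(
            f"dropped {dropped} zero-variance marker column(s); "
            f"p reduced to {int(keep.sum())}",
            stacklevel=2,
        )
        X = X[:, keep]
        sd = sd[keep]
    W = X - X.mean(axis=0) if center else X.copy()
    if standardize:
        W = W / sd
    p = W.shape[1]
    G = W @ W.T / p
    return RelationshipMatrix(G, markers.row_labels, kind="genomic_G")


def scaled_distances(markers: MarkerMatrix) -> DistanceMatrix:
    """Pairwise Euclidean distances on raw genotype codes, scaled by 1/sqrt(m).

    The square of entry (i, j) is then sum_k (x_ik - x_jk)^2 / m, the argument
    of the Gaussian kernel.
    """
    X = markers.imputed()
    m = X.shape[1]
    if m == 0:
        raise ValueError("no marker columns")
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.fill_diagonal(d2, 0.0)
    d2 = np.clip(d2, 0.0, None)
    s = np.sqrt(d2 / m)
    np.fill_diagonal(s, 0.0)
    return DistanceMatrix(s, markers.row_labels)


def gaussian_kernel(dist: DistanceMatrix, theta: float) -> RelationshipMatrix:
    """K(i, j) = exp(-theta * s_ij^2) on the scaled distances."""
    if theta < 0:
        raise ValueError("bandwidth theta must be nonnegative")
    K = np.exp(-theta * dist.values**2)
    np.fill_diagonal(K, 1.0)
    return RelationshipMatrix(K, dist.labels, kind="gaussian")


def exponential_kernel(dist: DistanceMatrix, theta: float) -> RelationshipMatrix:
    """K(i, j) = exp(-theta * s_ij) on the scaled distances (not squared)."""
    if theta < 0:
        raise ValueError("bandwidth theta must be nonnegative")
    K = np.exp(-theta * dist.values)
    np.fill_diagonal(K, 1.0)
    return RelationshipMatrix(K, dist.labels, kind="exponential")


def kron_kernel(
    K1: RelationshipMatrix, K2: RelationshipMatrix, label_sep: str = ":"
) -> RelationshipMatrix:
    """Kronecker product covariance for crosses, K1-major label order.

    The level for (a, b) is ``f"{a}{label_sep}{b}"``; entry for
    ((a, b), (a', b')) is K1(a, a') * K2(b, b').  This matches hybrid ids of
    the "Parent1:Parent2" form used in combining-ability models.
    """
    labels = [f"{a}{label_sep}{b}" for a in K1.labels for b in K2.labels]
    if len(set(labels)) != len(labels):
        raise ValueError("label collision after Kronecker concatenation")
    return RelationshipMatrix(np.kron(K1.values, K2.values), labels, kind="kronecker")


def factorize(K: RelationshipMatrix, method: str = "auto") -> CovFactor:
    """Factor K as L L' by Cholesky or eigendecomposition.

    ``method="auto"`` tries Cholesky (with a tiny jitter retry) and falls back
    to the eigen route when K is numerically rank-deficient.  Eigenvalues in
    [-1e-8 * lambda_max, 0) are clipped to zero; anything more negative is an
    error.  For the eigen route, L = Gamma * sqrt(Lambda) with columns ordered
    by decreasing eigenvalue.
    """
    if method not in {"cholesky", "eigen", "auto"}:
        raise ValueError(f"unknown factorization method {method!r}")
    M = K.values
    n = M.shape[0]

    def _chol() -> CovFactor:
        try:
            L = np.linalg.cholesky(M)
            return CovFactor(L, "cholesky", list(K.labels), {"n_clipped": 0, "jitter": 0.0})
        except np.linalg.LinAlgError:
            w = np.linalg.eigvalsh(M)
            lam_max = max(w.max(), 0.0)
            if w.min() < -PSD_RTOL * max(lam_max, 1e-300):
                raise np.linalg.LinAlgError(
                    f"matrix is indefinite: most negative eigenvalue {w.min():.3e}"
                )
            jitter = PSD_RTOL * max(lam_max, 1.0)
            L = np.linalg.cholesky(M + jitter * np.eye(n))
            return CovFactor(
                L,
                "cholesky",
                list(K.labels),
                {"n_clipped": int((w < 0).sum()), "jitter": jitter},
            )

    def _eigen() -> CovFactor:
        w, V = np.linalg.eigh(M)
        lam_max = max(w.max(), 0.0)
        floor = -PSD_RTOL * max(lam_max, 1e-300)
        if w.min() < floor:
            raise np.linalg.LinAlgError(
                f"matrix is indefinite beyond tolerance: most negative "
                f"eigenvalue {w.min():.3e} (limit {floor:.3e})"
            )
        n_clip = int((w < 0).sum())
        clip_mag = float(-w.min()) if n_clip else 0.0
        w = np.clip(w, 0.0, None)
        order = np.argsort(w)[::-1]
        L = V[:, order] * np.sqrt(w[order])
        return CovFactor(
            L, "eigen", list(K.labels), {"n_clipped": n_clip, "clip_magnitude": clip_mag}
        )

    if method == "cholesky":
        return _chol()
    if method == "eigen":
        return _eigen()
    # auto: plain Cholesky if K is numerically PD, else the eigen route
    try:
        L = np.linalg.cholesky(M)
        return CovFactor(L, "cholesky", list(K.labels), {"n_clipped": 0, "jitter": 0.0})
    except np.linalg.LinAlgError:
        return _eigen()
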