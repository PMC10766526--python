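"""Disease constellations by k-SVD dictionary learning.

The disease vectors are approximated as sparse combinations of K unit-norm
atoms ("constellations").  Fitting alternates orthogonal matching pursuit
(sparse coding) with atom-wise rank-1 SVD updates, so the Frobenius
reconstruction error never increases.  Each disease is then assigned to the
constellation of maximal cosine similarity.  A hierarchical-clustering
baseline (average linkage on 1 - cosine) and a hypergeometric overlap test
are provided to check the robustness of the partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .embedding import EmbeddingMatrix

__all__ = [
    "ConstellationDictionary",
    "fit_ksvd",
    "assign_diseases",
    "hierarchical_baseline",
    "overlap_test",
]


@dataclass
class ConstellationDictionary:
    """K unit-norm atoms plus the per-disease argmax-cosine assignment."""

    atoms: np.ndarray  # K x d, unit rows
    assignment: pd.DataFrame  # disease, constellation (1-based), cosine
    iterations: int
    final_error: float
    error_history: list[float]

    @property
    def K(self) -> int:
        return self.atoms.shape[0]


def _normalize_rows(X: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(X, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return X / n


def _farthest_point_init(Y: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Seed K atoms from normalized signals, greedily maximizing spread."""
    U = _normalize_rows(Y)
    first = int(rng.integers(len(U)))
    chosen = [first]
    # distance to chosen set measured as max |cosine| (sign-invariant)
    close = np.abs(U @ U[first])
    for _ in range(1, K):
        nxt = int(np.argmin(close))
        chosen.append(nxt)
        close = np.maximum(close, np.abs(U @ U[nxt]))
    return U[chosen].copy()


def _omp(D: np.ndarray, y: np.ndarray, sparsity: int) -> np.ndarray:
    """Orthogonal matching pursuit against unit-norm atoms (rows of D)."""
    K = D.shape[0]
    gamma = np.zeros(K)
    if sparsity == 1:  # closed form: best single signed atom
        proj = D @ y
        j = int(np.argmax(np.abs(proj)))
        gamma[j] = proj[j]
        return gamma
    residual = y.copy()
    support: list[int] = []
    for _ in range(sparsity):
        proj = D @ residual
        proj[support] = 0.0
        j = int(np.argmax(np.abs(proj)))
        support.append(j)
        sub = D[support]
        coef, *_ = np.linalg.lstsq(sub.T, y, rcond=None)
        residual = y - sub.T @ coef
    gamma[support] = coef
    return gamma


def fit_ksvd(
    E: EmbeddingMatrix,
    K: int = 10,
    sparsity: int = 1,
    max_iters: int = 50,
    tol: float = 1e-6,
    seed: int = 0,
) -> ConstellationDictionary:
    """Learn K constellation atoms from the disease vectors.

    Stops when the argmax-cosine assignment is unchanged for two consecutive
    iterations, the error change falls below ``tol``, or ``max_iters`` is
    reached.  Atoms left unused by the sparse code are re-seeded from the
    worst-reconstructed disease.
    """
    Y = E.coords
    n = Y.shape[0]
    if K >= n:
        raise ValueError("K must be smaller than the number of diseases")
    if sparsity > K:
        raise ValueError("sparsity cannot exceed K")
    rng = np.random.default_rng(seed)
    D = _farthest_point_init(Y, K, rng)

    errors: list[float] = []
    prev_assign: np.ndarray | None = None
    stable = 0
    it = 0
    for it in range(1, max_iters + 1):
        gamma = np.stack([_omp(D, y, sparsity) for y in Y])  # n x K

        # atom-wise SVD updates on restricted residuals
        for k in range(K):
            members = np.nonzero(gamma[:, k])[0]
            if members.size == 0:
                recon = gamma @ D
                worst = int(np.argmax(np.linalg.norm(Y - recon, axis=1)))
                v = Y[worst]
                nv = np.linalg.norm(v)
                if nv > 0:
                    D[k] = v / nv
                continue
            resid = Y[members] - gamma[members] @ D + np.outer(gamma[members, k], D[k])
            U, s, Vt = np.linalg.svd(resid, full_matrices=False)
            atom, coefs = Vt[0], U[:, 0] * s[0]
            if coefs.sum() < 0:  # SVD sign is arbitrary; point toward members
                atom, coefs = -atom, -coefs
            D[k] = atom
            gamma[members, k] = coefs

        err = float(np.linalg.norm(Y - gamma @ D))
        errors.append(err)

        assign = np.argmax(_normalize_rows(Y) @ D.T, axis=1)
        if prev_assign is not None and np.array_equal(assign, prev_assign):
            stable += 1
            if stable >= 2:
                break
        else:
            stable = 0
        if len(errors) >= 2 and abs(errors[-2] - errors[-1]) < tol:
            break
        prev_assign = assign

    D = _normalize_rows(D)
    dic = ConstellationDictionary(
        atoms=D,
        assignment=pd.DataFrame(),
        iterations=it,
        final_error=errors[-1],
        error_history=errors,
    )
    dic.assignment = assign_diseases(E, dic)
    return dic


def assign_diseases(E: EmbeddingMatrix, D: ConstellationDictionary) -> pd.DataFrame:
    """Assign every disease to its argmax-cosine constellation (1-based).

    Ties go to the lowest constellation index.
    """
    sims = _normalize_rows(E.coords) @ D.atoms.T
    best = np.argmax(sims, axis=1)  # argmax returns the first (lowest) index
    return pd.DataFrame(
        {
            "disease": list(E.tokens),
            "constellation": best + 1,
            "cosine": sims[np.arange(len(best)), best],
        }
    )


def hierarchical_baseline(E: EmbeddingMatrix, K: int) -> dict[str, int]:
    """Average-linkage agglomerative clustering on 1 - cosine, cut at K."""
    if K >= len(E.tokens) + 1:
        raise ValueError("K exceeds the number of diseases")
    dist = pdist(E.coords, metric="cosine")
    Z = linkage(dist, method="average")
    labels = fcluster(Z, t=K, criterion="maxclust")
    return dict(zip(E.tokens, (int(x) for x in labels)))


def overlap_test(
    partition_a: dict[str, int], partition_b: dict[str, int], N: int | None = None
) -> pd.DataFrame:
    """Greedy one-to-one cluster matching with hypergeometric p-values.

    Partitions map disease -> cluster label.  Pairs are matched largest
    overlap first; the per-pair p is the upper hypergeometric tail
    P(X >= overlap) with population ``N`` (default: the universe size),
    ``|cluster_b|`` successes and ``|cluster_a|`` draws.
    """
    if set(partition_a) != set(partition_b):
        raise ValueError("partitions cover different disease universes")
    if N is None:
        N = len(partition_a)
    clusters_a: dict[int, set[str]] = {}
    clusters_b: dict[int, set[str]] = {}
    for d, c in partition_a.items():
        clusters_a.setdefault(c, set()).add(d)
    for d, c in partition_b.items():
        clusters_b.setdefault(c, set()).add(d)

    pairs = [
        (len(sa & sb), la, lb)
        for la, sa in clusters_a.items()
        for lb, sb in clusters_b.items()
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    rows = []
    for k, la, lb in pairs:
        if la in used_a or lb in used_b:
            continue
        used_a.add(la)
        used_b.add(lb)
        na, nb = len(clusters_a[la]), len(clusters_b[lb])
        p = float(stats.hypergeom.sf(k - 1, N, nb, na))
        rows.append(
            {
                "cluster_a": la,
                "cluster_b": lb,
                "overlap": k,
                "size_a": na,
                "size_b": nb,
                "p": p,
            }
        )
    return pd.DataFrame(rows).sort_values("cluster_a").reset_index(drop=True)
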