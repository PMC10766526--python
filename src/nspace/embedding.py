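"""Disease embedding space: training, PCA rotation and space-level queries.

Diseases are embedded by predicting a held-out diagnosis from the diagnoses
surrounding it in a patient's chronological record (CBOW with negative
sampling, symmetric window).  The learned coordinates are then rotated with
principal component analysis so that dimension 1 carries the largest
variance, giving an orthogonal coordinate system in which dimensions can be
annotated and compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist

from .io_formats import DiagnosisCorpus, DiseaseVocabulary

__all__ = [
    "EmbeddingMatrix",
    "train_embeddings",
    "pca_rotate",
    "cosine_similarity",
    "neighbors",
    "analogy_query",
    "dimension_ordering",
    "rank_dimensions_by_loading",
    "compare_spaces",
]


@dataclass
class EmbeddingMatrix:
    """Diseases x dimensions coordinates plus training metadata.

    Row order follows the vocabulary's disease-group order.  After rotation
    the inter-dimension sample covariance is diagonal and per-dimension
    variances are non-increasing.
    """

    tokens: tuple[str, ...]
    coords: np.ndarray  # n_tokens x d
    rotated: bool = False
    dim_variance: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape[0] != len(self.tokens):
            raise ValueError("coordinate rows != token count")
        self._index = {t: i for i, t in enumerate(self.tokens)}

    @property
    def d(self) -> int:
        return self.coords.shape[1]

    def vector(self, token: str) -> np.ndarray:
        try:
            return self.coords[self._index[token]]
        except KeyError:
            raise KeyError(f"disease {token!r} not in embedding") from None

    def __contains__(self, token: str) -> bool:
        return token in self._index


def train_embeddings(
    corpus: DiagnosisCorpus,
    vocab: DiseaseVocabulary,
    d: int = 20,
    window: int = 8,
    seed: int = 0,
    epochs: int = 10,
    negative: int = 5,
    alpha: float = 0.025,
    min_alpha: float = 1e-4,
) -> EmbeddingMatrix:
    """Train the (unrotated) disease embedding.

    Every vocabulary disease receives a vector (minimum token count 1;
    diseases never observed keep their small random initialization).
    Single-threaded and bit-reproducible under ``seed``.
    """
    from ._cbow import build_negative_table, train_epochs

    if len(corpus) == 0:
        raise ValueError("empty corpus")
    if d >= len(vocab.groups):
        raise ValueError(
            f"embedding dimension d={d} must be smaller than the "
            f"vocabulary size {len(vocab.groups)}"
        )

    tokens = tuple(vocab.groups)
    index = {t: i for i, t in enumerate(tokens)}
    sents = corpus.sentences()
    flat = np.fromiter(
        (index[t] for s in sents for t in s), dtype=np.int32
    )
    offsets = np.zeros(len(sents) + 1, dtype=np.int64)
    np.cumsum([len(s) for s in sents], out=offsets[1:])

    counts = np.bincount(flat, minlength=len(tokens)).astype(np.float64)
    neg_table = build_negative_table(counts)

    rng = np.random.default_rng(seed)
    syn0 = (rng.random((len(tokens), d)) - 0.5) / d
    syn1 = np.zeros((len(tokens), d))
    objective = train_epochs(
        flat,
        offsets,
        syn0,
        syn1,
        neg_table,
        window,
        negative,
        epochs,
        alpha,
        min_alpha,
        seed,
    )
    return EmbeddingMatrix(
        tokens=tokens,
        coords=syn0,
        rotated=False,
        meta={
            "window": window,
            "d": d,
            "epochs": epochs,
            "seed": seed,
            "negative": negative,
            "final_objective": float(-objective),  # cost = -log-likelihood
        },
    )


def pca_rotate(E: EmbeddingMatrix) -> EmbeddingMatrix:
    """Rotate coordinates onto principal axes (centered scores).

    Dimension k carries the k-th largest variance; each component's sign is
    fixed so its largest-magnitude loading is positive.  The rotation is
    orthogonal, hence pairwise distances are preserved.
    """
    X = E.coords - E.coords.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each axis made positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U * s
    var = scores.var(axis=0, ddof=1)
    return replace(
        E,
        coords=scores,
        rotated=True,
        dim_variance=var,
        meta={**E.meta, "pca_components": Vt},
    )


def cosine_similarity(a: str, b: str, E: EmbeddingMatrix) -> float:
    va, vb = E.vector(a), E.vector(b)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(va @ vb / (na * nb))


def _cosine_to(target: np.ndarray, E: EmbeddingMatrix) -> np.ndarray:
    nt = np.linalg.norm(target)
    if nt == 0:
        raise ValueError("zero target vector")
    norms = np.linalg.norm(E.coords, axis=1)
    if (norms == 0).any():
        raise ValueError("embedding contains a zero vector")
    return E.coords @ target / (norms * nt)


def neighbors(
    a: str, E: EmbeddingMatrix, k: int, farthest: bool = False
) -> list[tuple[str, float]]:
    """The k nearest (or farthest) diseases by cosine, excluding the query.

    Ties are broken by vocabulary order (stable sort over row order).
    """
    if k >= len(E.tokens):
        raise ValueError("k must be smaller than the vocabulary size")
    sims = _cosine_to(E.vector(a), E)
    order = np.argsort(sims if farthest else -sims, kind="stable")
    qi = E._index[a]
    out = [(E.tokens[i], float(sims[i])) for i in order if i != qi]
    return out[:k]


def analogy_query(
    plus: list[str],
    minus: list[str],
    E: EmbeddingMatrix,
    k: int = 5,
) -> list[tuple[str, float]]:
    """Vector-algebra analogy: rank by cosine to sum(plus) - sum(minus)."""
    if not plus:
        raise ValueError("analogy needs at least one positive operand")
    target = np.sum([E.vector(t) for t in plus], axis=0)
    if minus:
        target = target - np.sum([E.vector(t) for t in minus], axis=0)
    sims = _cosine_to(target, E)
    exclude = {E._index[t] for t in list(plus) + list(minus)}
    order = np.argsort(-sims, kind="stable")
    out = [(E.tokens[i], float(sims[i])) for i in order if i not in exclude]
    return out[:k]


def dimension_ordering(i: int, E: EmbeddingMatrix) -> list[tuple[str, float]]:
    """Diseases ascending by their signed coordinate on 1-based dimension i."""
    if not 1 <= i <= E.d:
        raise ValueError(f"dimension {i} out of range 1..{E.d}")
    col = E.coords[:, i - 1]
    order = np.argsort(col, kind="stable")  # ties keep vocabulary order
    return [(E.tokens[j], float(col[j])) for j in order]


def rank_dimensions_by_loading(a, E: EmbeddingMatrix | None = None) -> list[int]:
    """1-based dimension indices ordered by |coordinate| descending.

    ``a`` may be a disease token (looked up in ``E``) or a raw coordinate
    vector.  Ties are broken by dimension index.
    """
    v = np.asarray(a, dtype=float) if E is None or not isinstance(a, str) else E.vector(a)
    order = np.argsort(-np.abs(v), kind="stable")
    return [int(j) + 1 for j in order]


def compare_spaces(
    E_a: EmbeddingMatrix, E_b: EmbeddingMatrix, metric: str = "euclidean"
) -> dict:
    """Concordance of two spaces over all disease-pair distances.

    Computes Pearson r over the C(n, 2) pairwise Euclidean distances (or
    cosine similarities) and a least-squares line with coefficient and
    intercept p-values.
    """
    if E_a.tokens != E_b.tokens:
        raise ValueError("embeddings cover different disease sets")
    if metric == "euclidean":
        va, vb = pdist(E_a.coords), pdist(E_b.coords)
    elif metric == "cosine":
        va, vb = 1.0 - pdist(E_a.coords, "cosine"), 1.0 - pdist(E_b.coords, "cosine")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    r, r_p = stats.pearsonr(va, vb)
    fit = stats.linregress(va, vb)
    # intercept p from the t statistic of the intercept estimate
    n = len(va)
    t_int = fit.intercept / fit.intercept_stderr if fit.intercept_stderr > 0 else np.inf
    p_int = 2 * stats.t.sf(abs(t_int), df=n - 2)
    return {
        "metric": metric,
        "n_pairs": n,
        "pearson_r": float(r),
        "pearson_p": float(r_p),
        "slope": float(fit.slope),
        "slope_p": float(fit.pvalue),
        "intercept": float(fit.intercept),
        "intercept_p": float(p_int),
    }
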