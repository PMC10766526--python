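"""Individuals as points in the disease space.

A patient's position is the diagnosis-count-weighted mean of their disease
vectors,

    E-bar_i = sum_w n_w E_i^w / sum_w n_w,

which turns each embedding dimension into a quantitative trait.  The module
also runs the phenotype-dimension association scan: each (min-max
normalized) phenotypic measure is regressed against every dimension trait
with covariate adjustment and BH-FDR control over the full family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .embedding import EmbeddingMatrix
from .io_formats import DiagnosisCorpus, DiagnosisHistory

__all__ = [
    "PatientEmbedding",
    "patient_embedding",
    "corpus_traits",
    "minmax_normalize",
    "phenotype_association",
]


@dataclass(frozen=True)
class PatientEmbedding:
    """One individual's trait vector (weighted-mean disease coordinates)."""

    patient_id: str
    traits: np.ndarray  # length d
    n_diagnoses: int

    def __post_init__(self) -> None:
        if self.n_diagnoses < 1:
            raise ValueError("patient embedding needs at least one diagnosis")


def patient_embedding(
    history: DiagnosisHistory, E: EmbeddingMatrix
) -> PatientEmbedding:
    """Count-weighted mean of the patient's disease vectors.

    Depends only on diagnosis counts, not event order or absolute counts
    scale; each coordinate lies within the min/max of the contributing
    disease coordinates.
    """
    counts = history.counts()
    usable = {t: c for t, c in counts.items() if t in E}
    if not usable:
        raise ValueError(
            f"patient {history.patient_id!r} has no diagnoses in the embedding"
        )
    total = sum(usable.values())
    vec = np.zeros(E.d)
    for t, c in usable.items():
        vec += c * E.vector(t)
    return PatientEmbedding(
        patient_id=history.patient_id, traits=vec / total, n_diagnoses=total
    )


def corpus_traits(corpus: DiagnosisCorpus, E: EmbeddingMatrix) -> pd.DataFrame:
    """Trait matrix for a whole corpus: one row per patient, columns T1..Td.

    Patients with no usable diagnoses are excluded.
    """
    rows = {}
    for h in corpus:
        try:
            pe = patient_embedding(h, E)
        except ValueError:
            continue
        rows[h.patient_id] = np.append(pe.traits, pe.n_diagnoses)
    cols = [f"T{i + 1}" for i in range(E.d)] + ["n_dx"]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.index.name = "patient_id"
    return df


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Rescale to [0, 1] as (x - min) / (max - min); constant input errors."""
    x = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        raise ValueError("min-max normalization undefined for constant input")
    return (x - lo) / (hi - lo)


def _drop_collinear(X: pd.DataFrame) -> pd.DataFrame:
    """Drop columns that add no rank (collinear covariates), keeping order."""
    keep: list[str] = []
    for col in X.columns:
        cand = X[keep + [col]].to_numpy()
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(col)
    return X[keep]


def phenotype_association(
    phenotypes: pd.DataFrame,
    traits: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    spirometry: set[str] | None = None,
    height_col: str = "height",
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Associate each phenotype with each dimension trait.

    Per (phenotype, dimension) pair an OLS model regresses the dimension
    trait on the min-max normalized phenotype plus covariates (complete
    cases only); ``height`` is added for phenotypes flagged as spirometry.
    The reported p is the t-test on the phenotype coefficient; q is BH over
    the full phenotype x dimension family.
    """
    spirometry = spirometry or set()
    trait_cols = [c for c in traits.columns if c.startswith("T")]
    rows = []
    for pheno in phenotypes.columns:
        cov = covariates
        if pheno in spirometry:
            if covariates is None or height_col not in covariates.columns:
                raise ValueError(
                    f"spirometry phenotype {pheno!r} requires a {height_col!r} covariate"
                )
            cov = covariates
        elif covariates is not None and height_col in covariates.columns:
            cov = covariates.drop(columns=[height_col])

        frames = [phenotypes[[pheno]], traits[trait_cols]]
        if cov is not None:
            frames.append(cov)
        df = pd.concat(frames, axis=1, join="inner").dropna()
        x = minmax_normalize(df[pheno].to_numpy())
        design = pd.DataFrame({"const": 1.0, "phenotype": x}, index=df.index)
        if cov is not None:
            design = pd.concat([design, df[cov.columns]], axis=1)
            design = _drop_collinear(design)
        for tcol in trait_cols:
            fit = sm.OLS(df[tcol].to_numpy(), design.to_numpy()).fit()
            j = list(design.columns).index("phenotype")
            rows.append(
                {
                    "phenotype": pheno,
                    "dimension": int(tcol[1:]),
                    "beta": fit.params[j],
                    "se": fit.bse[j],
                    "p": fit.pvalues[j],
                    "n": int(fit.nobs),
                }
            )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < fdr
    return out
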