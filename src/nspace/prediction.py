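"""Polygenic prediction of single diseases and disease constellations.

Polygenic risk scores follow S_i = sum_j X_ij beta_j over effect-allele
dosages; a "universal" profile holds one score per embedding dimension,
shared by every disease target.  Three models are compared: a logistic GLM
on a disease-specific score (catalog weights), a GLM on the universal
profile, and a gradient-boosted classifier on the universal profile.  Each
repeat draws balanced case/control train and test sets without replacement;
goodness of fit is Nagelkerke R^2 with a likelihood-ratio p (null model:
covariates only), and test-set performance is accuracy, PPV and NPV.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier

from .io_formats import DiagnosisCorpus, GenotypeMatrix, WeightTable

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionReport",
    "compute_prs",
    "nagelkerke_r2",
    "classification_metrics",
    "label_constellations",
    "fit_predict",
]


def compute_prs(G: GenotypeMatrix, W: WeightTable) -> pd.DataFrame:
    """Per-tag polygenic scores S_i = sum_j X_ij beta_j.

    Effect alleles are reconciled against the genotype matrix: when the
    weight's effect allele is the matrix's other allele, the dosage is
    recoded as 2 - X.  Weight rows whose variant is absent or whose alleles
    match neither are dropped with a logged tally; a tag with no usable
    variants is an error.
    """
    idx_of = {v: i for i, v in enumerate(G.variants["id"])}
    ea = G.variants["ea"].to_numpy()
    oa = G.variants["oa"].to_numpy()
    scores: dict[str, np.ndarray] = {}
    for tag in W.tags:
        sub = W.for_tag(tag)
        s = np.zeros(G.n_samples)
        used = dropped = 0
        for r in sub.itertuples(index=False):
            j = idx_of.get(r.variant)
            if j is None:
                dropped += 1
                continue
            if r.effect_allele == ea[j]:
                dose = G.dosages[:, j]
            elif r.effect_allele == oa[j]:
                dose = 2.0 - G.dosages[:, j]
            else:
                dropped += 1
                continue
            s += dose * r.beta
            used += 1
        if used == 0:
            raise ValueError(f"no usable variants for tag {tag!r}")
        if dropped:
            logger.warning("tag %r: dropped %d unusable weight rows", tag, dropped)
        scores[tag] = s
    return pd.DataFrame(scores, index=pd.Index(G.sample_ids, name="patient_id"))


def nagelkerke_r2(
    loglik_null: float, loglik_full: float, n: int, df_diff: int = 1
) -> tuple[float, float]:
    """Nagelkerke R^2 and likelihood-ratio p.

    Cox-Snell R^2 = 1 - exp(2(l0 - l1)/n), rescaled by its maximum
    1 - exp(2 l0 / n); the LR statistic 2(l1 - l0) is chi-square with
    ``df_diff`` degrees of freedom.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if loglik_full < loglik_null - 1e-9:
        raise ValueError("full-model log-likelihood below the null's")
    cox_snell = 1.0 - np.exp(2.0 * (loglik_null - loglik_full) / n)
    max_cs = 1.0 - np.exp(2.0 * loglik_null / n)
    r2 = float(cox_snell / max_cs) if max_cs > 0 else 0.0
    lr = max(2.0 * (loglik_full - loglik_null), 0.0)
    p = float(stats.chi2.sf(lr, df=df_diff))
    return r2, p


def classification_metrics(
    truth: np.ndarray, predicted: np.ndarray
) -> tuple[float, float, float]:
    """(accuracy, PPV, NPV) on binary labels; undefined rates are NaN."""
    t = np.asarray(truth).astype(bool)
    p = np.asarray(predicted).astype(bool)
    if t.shape != p.shape:
        raise ValueError("label vectors differ in length")
    tp = int((t & p).sum())
    tn = int((~t & ~p).sum())
    fp = int((~t & p).sum())
    fn = int((t & ~p).sum())
    accuracy = (tp + tn) / len(t)
    if tp + fp == 0:
        warnings.warn("no positive predictions; PPV undefined", stacklevel=2)
        ppv = float("nan")
    else:
        ppv = tp / (tp + fp)
    if tn + fn == 0:
        warnings.warn("no negative predictions; NPV undefined", stacklevel=2)
        npv = float("nan")
    else:
        npv = tn / (tn + fn)
    return accuracy, ppv, npv


def label_constellations(
    corpus: DiagnosisCorpus, assignment: pd.DataFrame
) -> dict[str, set[int]]:
    """Label each patient with every constellation their diseases belong to.

    ``assignment`` maps disease -> constellation (the argmax-cosine table);
    labels are the union over the patient's distinct diseases.
    """
    of = dict(zip(assignment["disease"], assignment["constellation"]))
    out: dict[str, set[int]] = {}
    for h in corpus:
        labels = set()
        for t in set(h.tokens):
            if t not in of:
                raise ValueError(f"disease {t!r} has no constellation assignment")
            labels.add(int(of[t]))
        out[h.patient_id] = labels
    return out


@dataclass
class PredictionReport:
    """Mean and empirical 95% CI of each metric over the repeats."""

    target: str
    model: str
    repeats: int
    n_train_per_arm: int
    n_test_per_arm: int
    r2_mean: float
    r2_ci: tuple[float, float]
    lr_p_median: float
    accuracy_mean: float
    accuracy_ci: tuple[float, float]
    ppv_mean: float
    ppv_ci: tuple[float, float]
    npv_mean: float
    npv_ci: tuple[float, float]
    per_repeat: pd.DataFrame


def _ci(values: np.ndarray) -> tuple[float, float]:
    v = values[np.isfinite(values)]
    return (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))


def _draw_split(
    rng: np.random.Generator,
    cases: np.ndarray,
    controls: np.ndarray,
    n_train_per_arm: int,
    n_test_per_arm: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint balanced train/test draws without replacement."""
    tr = np.concatenate(
        [
            rng.choice(cases, n_train_per_arm, replace=False),
            rng.choice(controls, n_train_per_arm, replace=False),
        ]
    )
    tr_set = set(tr)
    rem_cases = np.array([c for c in cases if c not in tr_set])
    rem_controls = np.array([c for c in controls if c not in tr_set])
    te = np.concatenate(
        [
            rng.choice(rem_cases, n_test_per_arm, replace=False),
            rng.choice(rem_controls, n_test_per_arm, replace=False),
        ]
    )
    return tr, te


def _fit_logit(y: np.ndarray, X: np.ndarray) -> sm.discrete.discrete_model.BinaryResults:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.Logit(y, X).fit(disp=0, method="lbfgs", maxiter=500)


def fit_predict(
    case_status: pd.Series,
    features: pd.DataFrame,
    model: str = "glm",
    covariates: pd.DataFrame | None = None,
    target: str = "disease",
    n_train_per_arm: int = 5000,
    n_test_per_arm: int = 2500,
    repeats: int = 100,
    seed: int = 0,
    gbm_params: dict | None = None,
) -> PredictionReport:
    """Repeated balanced train/test evaluation of a polygenic model.

    ``case_status`` is a 0/1 series indexed by patient id; ``features`` the
    PRS columns (disease-specific scalar or the universal per-dimension
    profile).  Per repeat, ``n_train_per_arm`` cases and controls are drawn
    without replacement for training and ``n_test_per_arm`` of each from the
    remainder for testing; train and test sets are disjoint.  Nagelkerke
    R^2 compares the train fit against a covariates-only null.
    """
    if model not in {"glm", "gbm"}:
        raise ValueError(f"unknown model {model!r}")
    ids = features.index
    if covariates is not None:
        ids = ids.intersection(covariates.index)
    ids = ids.intersection(case_status.index)
    status = case_status.loc[ids].astype(int)
    cases = np.asarray(ids[status == 1])
    controls = np.asarray(ids[status == 0])
    need = n_train_per_arm + n_test_per_arm
    if len(cases) < need or len(controls) < need:
        raise ValueError(
            f"need {need} cases and controls; have {len(cases)} cases "
            f"and {len(controls)} controls"
        )

    feat_cols = list(features.columns)
    cov_cols = list(covariates.columns) if covariates is not None else []

    def design(sel_ids: np.ndarray, with_features: bool) -> np.ndarray:
        parts = [np.ones((len(sel_ids), 1))]
        if with_features:
            parts.append(features.loc[sel_ids, feat_cols].to_numpy(dtype=float))
        if cov_cols:
            parts.append(covariates.loc[sel_ids, cov_cols].to_numpy(dtype=float))
        return np.hstack(parts)

    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(repeats):
        tr, te = _draw_split(rng, cases, controls, n_train_per_arm, n_test_per_arm)
        y_tr = status.loc[tr].to_numpy()
        y_te = status.loc[te].to_numpy()

        X_null = design(tr, with_features=False)
        ll_null = _fit_logit(y_tr, X_null).llf

        if model == "glm":
            fit = _fit_logit(y_tr, design(tr, with_features=True))
            ll_full = fit.llf
            pred = fit.predict(design(te, with_features=True)) >= 0.5
        else:
            params = {
                "n_estimators": 500,
                "max_depth": 3,
                "learning_rate": 0.05,
                "subsample": 1.0,
                **(gbm_params or {}),
            }
            gbm = GradientBoostingClassifier(
                random_state=int(rng.integers(2**31)), **params
            )
            Xf_tr = np.hstack(
                [
                    features.loc[tr, feat_cols].to_numpy(dtype=float),
                    covariates.loc[tr, cov_cols].to_numpy(dtype=float)
                    if cov_cols
                    else np.empty((len(tr), 0)),
                ]
            )
            Xf_te = np.hstack(
                [
                    features.loc[te, feat_cols].to_numpy(dtype=float),
                    covariates.loc[te, cov_cols].to_numpy(dtype=float)
                    if cov_cols
                    else np.empty((len(te), 0)),
                ]
            )
            gbm.fit(Xf_tr, y_tr)
            prob_tr = np.clip(gbm.predict_proba(Xf_tr)[:, 1], 1e-12, 1 - 1e-12)
            ll_full = float(
                np.sum(y_tr * np.log(prob_tr) + (1 - y_tr) * np.log(1 - prob_tr))
            )
            ll_full = max(ll_full, ll_null)  # boosted fit dominates the null
            pred = gbm.predict_proba(Xf_te)[:, 1] >= 0.5

        r2, lr_p = nagelkerke_r2(
            ll_null, ll_full, n=len(y_tr), df_diff=len(feat_cols)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            acc, ppv, npv = classification_metrics(y_te, pred)
        rows.append(
            {"repeat": rep, "r2": r2, "lr_p": lr_p, "accuracy": acc, "ppv": ppv, "npv": npv}
        )

    per = pd.DataFrame(rows)
    return PredictionReport(
        target=target,
        model=model,
        repeats=repeats,
        n_train_per_arm=n_train_per_arm,
        n_test_per_arm=n_test_per_arm,
        r2_mean=float(per["r2"].mean()),
        r2_ci=_ci(per["r2"].to_numpy()),
        lr_p_median=float(per["lr_p"].median()),
        accuracy_mean=float(per["accuracy"].mean()),
        accuracy_ci=_ci(per["accuracy"].to_numpy()),
        ppv_mean=float(per["ppv"].mean()),
        ppv_ci=_ci(per["ppv"].to_numpy()),
        npv_mean=float(per["npv"].mean()),
        npv_ci=_ci(per["npv"].to_numpy()),
        per_repeat=per,
    )
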