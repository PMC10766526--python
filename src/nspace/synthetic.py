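"""Synthetic cohorts with the co-occurrence and genetic structure the
pipeline assumes.

The generative model is a per-patient category mixture.  Each patient draws a
base preference over disease categories from a symmetric Dirichlet; one or
more genetic latent axes (weighted sums of causal-variant dosages plus noise)
shift that preference through a fixed per-category loading pattern.  Diagnosis
tokens are drawn category-first, then uniformly within category, at strictly
increasing dates.  Genotypes are biallelic dosages in Hardy-Weinberg
proportions with independent variants.

Everything is deterministic under ``SimulationConfig.seed``; the ground truth
(disease-to-category map, causal effects, per-patient latent values) is
returned alongside the data so tests can assert recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    DiseaseVocabulary,
    DiagnosisCorpus,
    DiagnosisHistory,
    GenotypeMatrix,
    write_vocabulary,
    write_histories,
    write_dosages_tsv,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "make_vocabulary",
    "simulate_genotypes",
    "simulate_cohort",
    "make_fixture_bundle",
]

# role constants mixed into the seed so each stage has its own stream
_SEED_VOCAB, _SEED_GENO, _SEED_COHORT = 11, 23, 37


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort generator.

    ``effect_size_per_causal`` is the per-allele effect of one causal variant
    on its latent axis, in units of the (unit-variance) axis; the planted
    axis heritability is the sum of squared effects.  ``axis_loading`` scales
    how strongly the latent axis tilts a patient's category preference.
    """

    n_diseases: int = 60
    n_categories: int = 6
    n_patients: int = 5000
    mean_history_length: float = 12.0
    n_variants: int = 100
    n_causal_variants: int = 10
    effect_size_per_causal: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)
    affinity_concentration: float = 0.5
    axis_loading: float = 2.0
    n_latent_axes: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal_variants > self.n_variants:
            raise ValueError("n_causal_variants exceeds n_variants")
        for name in (
            "n_diseases",
            "n_categories",
            "n_patients",
            "n_variants",
            "n_latent_axes",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_diseases < self.n_categories:
            raise ValueError("need at least one disease per category")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator for downstream assertions."""

    config: SimulationConfig
    disease_category: dict[str, str] = field(default_factory=dict)
    causal: pd.DataFrame | None = None  # variant, axis, beta
    latent: np.ndarray | None = None  # n_patients x n_axes
    patient_ids: list[str] = field(default_factory=list)


def _rng(cfg: SimulationConfig, role: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, role])


def make_vocabulary(
    cfg: SimulationConfig,
) -> tuple[DiseaseVocabulary, SyntheticTruth]:
    """Partition ``n_diseases`` near-evenly across ``n_categories``.

    The first ``n_diseases mod n_categories`` categories receive one extra
    disease.  Tokens are deterministic (no randomness is consumed).
    """
    sizes = np.full(cfg.n_categories, cfg.n_diseases // cfg.n_categories)
    sizes[: cfg.n_diseases % cfg.n_categories] += 1
    entries: dict[str, tuple[str, str]] = {}
    truth = SyntheticTruth(config=cfg)
    k = 0
    for c in range(cfg.n_categories):
        cat = f"cat{c + 1:02d}"
        for _ in range(sizes[c]):
            group = f"D{k + 1:03d}"
            entries[f"C{k + 1:03d}"] = (group, cat)
            truth.disease_category[group] = cat
            k += 1
    vocab = DiseaseVocabulary(
        entries=entries,
        groups=tuple(g for g, _ in entries.values()),
        categories=tuple(f"cat{c + 1:02d}" for c in range(cfg.n_categories)),
    )
    return vocab, truth


def simulate_genotypes(cfg: SimulationConfig) -> GenotypeMatrix:
    """HWE genotypes: MAF ~ Uniform(maf_range), dosage ~ Binomial(2, p)."""
    rng = _rng(cfg, _SEED_GENO)
    maf = rng.uniform(*cfg.maf_range, size=cfg.n_variants)
    dos = rng.binomial(2, maf[None, :], size=(cfg.n_patients, cfg.n_variants))
    variants = pd.DataFrame(
        {
            "id": [f"rs{j + 1}" for j in range(cfg.n_variants)],
            "chrom": "1",
            "pos": np.arange(1, cfg.n_variants + 1) * 1_000_000,
            "ea": "A",
            "oa": "G",
        }
    )
    samples = [f"P{i + 1:06d}" for i in range(cfg.n_patients)]
    return GenotypeMatrix(
        sample_ids=samples, variants=variants, dosages=dos.astype(float)
    )


def _loading_pattern(n_axes: int, n_categories: int) -> np.ndarray:
    """Fixed +/-1 sign patterns (one per axis) over categories, zero-mean
    when the category count is even; patterns differ across axes."""
    pat = np.empty((n_axes, n_categories))
    for a in range(n_axes):
        half = max(1, n_categories // (2 ** (a + 1)))
        signs = np.array([1 if (c // half) % 2 == 0 else -1 for c in range(n_categories)])
        pat[a] = signs - signs.mean()
    return pat


def simulate_cohort(
    cfg: SimulationConfig,
    vocab_truth: tuple[DiseaseVocabulary, SyntheticTruth],
    genotypes: GenotypeMatrix,
) -> tuple[DiagnosisCorpus, SyntheticTruth]:
    """Draw diagnosis histories whose category mixture tracks the genetic
    latent axes."""
    vocab, truth = vocab_truth
    if genotypes.n_samples != cfg.n_patients:
        raise ValueError("genotype sample count != n_patients")
    rng = _rng(cfg, _SEED_COHORT)

    # genetic latent axes: standardized causal dosages times per-variant beta
    n_axes = cfg.n_latent_axes
    causal_idx = rng.choice(cfg.n_variants, size=cfg.n_causal_variants, replace=False)
    causal_idx.sort()
    axis_of = np.arange(cfg.n_causal_variants) % n_axes
    X = genotypes.dosages[:, causal_idx]
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    latent = np.empty((cfg.n_patients, n_axes))
    beta = np.full(cfg.n_causal_variants, cfg.effect_size_per_causal)
    for a in range(n_axes):
        sel = axis_of == a
        g = Xs[:, sel] @ beta[sel]
        h2 = float((beta[sel] ** 2).sum())
        noise_sd = np.sqrt(max(1.0 - h2, 0.0))
        latent[:, a] = g + rng.normal(0.0, noise_sd, size=cfg.n_patients)

    truth.causal = pd.DataFrame(
        {
            "variant": genotypes.variants["id"].to_numpy()[causal_idx],
            "axis": axis_of,
            "beta": beta,
        }
    )
    truth.latent = latent
    truth.patient_ids = list(genotypes.sample_ids)

    # per-patient category preference
    base = rng.dirichlet(
        np.full(cfg.n_categories, cfg.affinity_concentration), size=cfg.n_patients
    )
    loadings = _loading_pattern(n_axes, cfg.n_categories)  # n_axes x n_cat
    logits = np.log(base + 1e-12) + cfg.axis_loading * (latent @ loadings)
    logits -= logits.max(axis=1, keepdims=True)
    affinity = np.exp(logits)
    affinity /= affinity.sum(axis=1, keepdims=True)

    # diseases grouped by category, in vocabulary order
    by_cat: dict[str, list[str]] = {c: [] for c in vocab.categories}
    for g in vocab.groups:
        by_cat[vocab.group_category[g]].append(g)
    cat_lists = [by_cat[c] for c in vocab.categories]

    lengths = 1 + rng.poisson(max(cfg.mean_history_length - 1.0, 0.0), cfg.n_patients)
    corpus = DiagnosisCorpus()
    t0 = date(2000, 1, 1)
    for i, pid in enumerate(genotypes.sample_ids):
        L = int(lengths[i])
        cats = rng.choice(cfg.n_categories, size=L, p=affinity[i])
        toks = [
            cat_lists[c][rng.integers(len(cat_lists[c]))] for c in cats
        ]
        gaps = rng.uniform(7, 180, size=L)
        days = np.cumsum(gaps).astype(int)
        events = tuple(
            (t0 + timedelta(days=int(d)), t) for d, t in zip(days, toks)
        )
        corpus.histories[pid] = DiagnosisHistory(patient_id=pid, events=events)
    return corpus, truth


def make_fixture_bundle(cfg: SimulationConfig, out_dir) -> dict[str, Path]:
    """Write vocabulary, histories, genotypes and truth to ``out_dir``.

    All files are re-readable by :mod:`nspace.io_formats`; regenerating with
    the same config is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vocab, truth0 = make_vocabulary(cfg)
    geno = simulate_genotypes(cfg)
    corpus, truth = simulate_cohort(cfg, (vocab, truth0), geno)

    paths = {
        "vocabulary": out / "vocabulary.tsv",
        "histories": out / "histories.tsv",
        "genotypes": out / "genotypes.tsv",
        "truth": out / "truth.json",
    }
    write_vocabulary(vocab, paths["vocabulary"])
    write_histories(corpus, vocab, paths["histories"])
    write_dosages_tsv(geno, paths["genotypes"])

    truth_doc = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        },
        "disease_category": truth.disease_category,
        "causal": truth.causal.to_dict(orient="records"),
        "latent": [[round(float(x), 10) for x in row] for row in truth.latent],
        "patient_ids": truth.patient_ids,
    }
    paths["truth"].write_text(json.dumps(truth_doc, indent=1, sort_keys=True))
    return paths
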