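"""Genetic association scan over embedding-dimension traits.

Each dimension trait is regressed on additive effect-allele dosage with
covariate adjustment (equivalent to full OLS via residualization, so the
per-variant scan is vectorized).  Variants pass QC at MAF > 0.01 and
Hardy-Weinberg chi-square p > 1e-6; genome-wide significance defaults to
p < 5e-8.  Significant variants are collapsed to lead loci greedily by
ascending p, absorbing neighbors within +/-5,000 bp or in linkage
disequilibrium (dosage r^2 > 0.1).  Replication uses one-sided p-values
oriented by the discovery effect sign, BH-adjusted at 5% FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GenotypeMatrix

__all__ = [
    "LeadLocus",
    "qc_filter",
    "gwas_scan",
    "select_lead_loci",
    "replicate",
    "enrichment_test",
    "suggestive_genes",
    "genomic_control_lambda",
]

GENOME_WIDE_P = 5e-8


@dataclass
class LeadLocus:
    """A lead variant and the significant variants it absorbed."""

    dimension: int
    variant: str
    chrom: str
    pos: int
    p: float
    beta: float
    members: list[str] = field(default_factory=list)


def qc_filter(
    G: GenotypeMatrix, maf_min: float = 0.01, hwe_p_min: float = 1e-6
) -> GenotypeMatrix:
    """Drop variants with MAF <= maf_min or HWE chi-square p <= hwe_p_min."""
    keep = (G.maf > maf_min) & (G.hwe_p > hwe_p_min)
    return G.subset_variants(keep)


def _residualize(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of y (vector or matrix columns) on the column space of Z."""
    coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return y - Z @ coef


def gwas_scan(
    G: GenotypeMatrix,
    traits: pd.DataFrame,
    covariates: pd.DataFrame | None,
    dimension: int,
) -> pd.DataFrame:
    """Per-variant OLS of a dimension trait on dosage plus covariates.

    ``traits`` is indexed by patient id with columns T1..Td.  Samples are
    aligned by id across genotypes, traits and covariates.  Monomorphic
    variants are skipped (p = NaN).  Returns a summary-statistics frame
    with columns variant, chrom, pos, ea, beta, se, p, n, dimension.
    """
    ids = [s for s in G.sample_ids if s in traits.index]
    if covariates is not None:
        ids = [s for s in ids if s in covariates.index]
    if not ids:
        raise ValueError("no overlapping samples between genotypes and traits")
    pos_of = {s: i for i, s in enumerate(G.sample_ids)}
    rows = np.fromiter((pos_of[s] for s in ids), dtype=int)
    X = G.dosages[rows]
    y = traits.loc[ids, f"T{dimension}"].to_numpy(dtype=float)
    n = len(ids)

    if covariates is not None:
        Z = np.column_stack([np.ones(n), covariates.loc[ids].to_numpy(dtype=float)])
    else:
        Z = np.ones((n, 1))
    p_cov = np.linalg.matrix_rank(Z)
    df = n - p_cov - 1

    y_r = _residualize(y, Z)
    X_r = _residualize(X, Z)

    ss = (X_r**2).sum(axis=0)
    mono = ss <= 1e-12
    ss_safe = np.where(mono, 1.0, ss)
    beta = X_r.T @ y_r / ss_safe
    rss = (y_r**2).sum() - beta**2 * ss_safe
    sigma2 = np.maximum(rss, 0.0) / df
    se = np.sqrt(sigma2 / ss_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df=df)
    beta[mono] = np.nan
    se[mono] = np.nan
    p[mono] = np.nan

    out = G.variants[["id", "chrom", "pos", "ea"]].rename(columns={"id": "variant"})
    return out.assign(beta=beta, se=se, p=p, n=n, dimension=dimension)


def genomic_control_lambda(p_values: np.ndarray) -> float:
    """Median chi-square of the scan over its null expectation (0.4549)."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))


def select_lead_loci(
    results: pd.DataFrame,
    G: GenotypeMatrix,
    p_threshold: float = GENOME_WIDE_P,
    window_bp: int = 5000,
    r2_threshold: float = 0.1,
) -> list[LeadLocus]:
    """Collapse significant variants to lead loci, per dimension.

    Greedy by ascending p: a variant becomes a lead unless it lies within
    ``window_bp`` of an existing lead on the same chromosome or its dosage
    r^2 with one exceeds ``r2_threshold`` (then it is absorbed).  Output is
    invariant to input row order (ties broken by chromosome and position).
    """
    dos_of = {v: i for i, v in enumerate(G.variants["id"])}
    leads: list[LeadLocus] = []
    sig = results[results["p"] < p_threshold].copy()
    sig = sig.sort_values(["dimension", "p", "chrom", "pos"], kind="stable")
    for dim, sub in sig.groupby("dimension", sort=True):
        dim_leads: list[LeadLocus] = []
        for r in sub.itertuples(index=False):
            absorbed_by = None
            for lead in dim_leads:
                near = lead.chrom == r.chrom and abs(lead.pos - r.pos) <= window_bp
                r2 = 0.0
                if not near and r.variant in dos_of and lead.variant in dos_of:
                    a = G.dosages[:, dos_of[lead.variant]]
                    b = G.dosages[:, dos_of[r.variant]]
                    if a.std() > 0 and b.std() > 0:
                        r2 = float(np.corrcoef(a, b)[0, 1] ** 2)
                if near or r2 > r2_threshold:
                    absorbed_by = lead
                    break
            if absorbed_by is None:
                dim_leads.append(
                    LeadLocus(
                        dimension=int(dim),
                        variant=r.variant,
                        chrom=r.chrom,
                        pos=int(r.pos),
                        p=float(r.p),
                        beta=float(r.beta),
                    )
                )
            else:
                absorbed_by.members.append(r.variant)
        leads.extend(dim_leads)
    return leads


def replicate(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Directional replication of discovery associations.

    Both frames need columns variant, dimension, beta, p.  Associations
    absent from the replication scan are excluded and counted.  The
    one-sided p is half the replication two-sided p when the effect signs
    match and one minus that otherwise; BH is applied over the tested set.
    """
    key = ["variant", "dimension"]
    merged = discovery[key + ["beta", "p"]].merge(
        replication[key + ["beta", "p"]],
        on=key,
        how="left",
        suffixes=("_disc", "_rep"),
    )
    missing = merged["beta_rep"].isna()
    tested = merged[~missing].copy()
    concordant = np.sign(tested["beta_disc"]) == np.sign(tested["beta_rep"])
    p_two = tested["p_rep"].to_numpy()
    p_one = np.where(concordant, p_two / 2.0, 1.0 - p_two / 2.0)
    tested["direction_concordant"] = concordant.to_numpy()
    tested["p_one_sided"] = p_one
    tested["q"] = multipletests(p_one, method="fdr_bh")[1]
    tested["replicated"] = tested["q"] < fdr
    summary = {
        "n_discovery": int(len(merged)),
        "n_missing_in_replication": int(missing.sum()),
        "n_tested": int(len(tested)),
        "n_direction_concordant": int(concordant.sum()),
        "n_replicated": int(tested["replicated"].sum()),
    }
    return tested.reset_index(drop=True), summary


def suggestive_genes(
    results: pd.DataFrame,
    snp_gene_map: pd.DataFrame,
    suggestive_p: float = 1e-5,
) -> set[str]:
    """Genes mapped from variants passing the suggestive threshold.

    ``snp_gene_map`` needs columns ``variant`` and ``gene`` (for example a
    nearest-gene table).
    """
    hits = set(results.loc[results["p"] < suggestive_p, "variant"])
    return set(snp_gene_map.loc[snp_gene_map["variant"].isin(hits), "gene"])


def enrichment_test(
    query_genes: set[str],
    gene_sets: dict[str, set[str]],
    background: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment with BH correction across sets.

    The query must be a subset of the background; gene sets are intersected
    with the background before testing.
    """
    if not query_genes:
        raise ValueError("empty query gene set")
    if not query_genes <= background:
        raise ValueError("query genes not contained in background")
    N, q = len(background), len(query_genes)
    rows = []
    for name, genes in gene_sets.items():
        gset = genes & background
        k = len(query_genes & gset)
        p = float(stats.hypergeom.sf(k - 1, N, len(gset), q)) if gset else 1.0
        rows.append(
            {"gene_set": name, "set_size": len(gset), "overlap": k, "p": p}
        )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < alpha
    return out
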