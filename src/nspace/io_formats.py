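"""Readers and writers for the tables the pipeline exchanges.

All tabular formats are tab-separated UTF-8 text with a header row:

* vocabulary.tsv — ``code``, ``disease_group``, ``category``
* histories.tsv  — ``patient_id``, ``date`` (ISO-8601), ``code``
* weights.tsv    — ``variant``, ``effect_allele``, ``beta``, ``tag``
* dosage TSV     — ``sample_id`` column followed by one column per variant,
  variant columns named ``id:chrom:pos:ea:oa``

Genotypes may alternatively be read from an uncompressed VCF 4.x file
(``GT`` hard calls or ``DS`` dosages).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DiseaseVocabulary",
    "DiagnosisHistory",
    "DiagnosisCorpus",
    "GenotypeMatrix",
    "WeightTable",
    "read_vocabulary",
    "write_vocabulary",
    "read_histories",
    "write_histories",
    "read_dosages",
    "write_dosages_tsv",
    "read_weights",
    "write_weights",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiseaseVocabulary:
    """Flat mapping of diagnosis codes to disease groups to categories.

    A code belongs to exactly one disease group and every group to exactly
    one functional category; groups and categories are kept in first-seen
    order so downstream matrices have a stable row order.
    """

    entries: dict[str, tuple[str, str]]
    groups: tuple[str, ...]
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("duplicate disease groups in vocabulary")
        if len(set(self.categories)) != len(self.categories):
            raise ValueError("duplicate categories in vocabulary")
        seen: dict[str, str] = {}
        for code, (group, category) in self.entries.items():
            if not category:
                raise ValueError(f"empty category for code {code!r}")
            if group in seen and seen[group] != category:
                raise ValueError(f"group {group!r} mapped to two categories")
            seen[group] = category

    def group_of(self, code: str) -> str:
        return self.entries[code][0]

    def category_of(self, group: str) -> str:
        for g, c in self.entries.values():
            if g == group:
                return c
        raise KeyError(group)

    @property
    def group_category(self) -> dict[str, str]:
        """Disease-group token -> category token."""
        return {g: c for g, c in self.entries.values()}

    def __contains__(self, group: str) -> bool:
        return group in set(self.groups)


@dataclass(frozen=True)
class DiagnosisHistory:
    """One patient's chronologically ordered disease-group tokens."""

    patient_id: str
    events: tuple[tuple[_date, str], ...]

    def __post_init__(self) -> None:
        dates = [d for d, _ in self.events]
        if any(b < a for a, b in zip(dates, dates[1:])):
            raise ValueError(f"events of {self.patient_id!r} not date-sorted")

    @property
    def tokens(self) -> list[str]:
        return [t for _, t in self.events]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, t in self.events:
            out[t] = out.get(t, 0) + 1
        return out


@dataclass
class DiagnosisCorpus:
    """Ordered collection of patient histories; the training sentences."""

    histories: dict[str, DiagnosisHistory] = field(default_factory=dict)
    n_unknown_codes: int = 0

    def __len__(self) -> int:
        return len(self.histories)

    def __iter__(self):
        return iter(self.histories.values())

    def sentences(self) -> list[list[str]]:
        return [h.tokens for h in self.histories.values()]


@dataclass
class GenotypeMatrix:
    """Biallelic dosages on ``n_samples x n_variants`` with variant metadata.

    ``variants`` carries columns ``id, chrom, pos, ea, oa``; ``dosages`` holds
    effect-allele counts in [0, 2] (fractional after imputation).  MAF and a
    Hardy-Weinberg chi-square p-value are computed lazily and cached.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    _maf: np.ndarray | None = field(default=None, repr=False)
    _hwe_p: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError("dosage matrix shape mismatch")
        if self.dosages.size and (
            self.dosages.min() < -1e-9 or self.dosages.max() > 2 + 1e-9
        ):
            raise ValueError("dosages outside [0, 2]")
        if (self.variants["pos"] <= 0).any():
            raise ValueError("variant positions must be positive")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def maf(self) -> np.ndarray:
        if self._maf is None:
            p = self.dosages.mean(axis=0) / 2.0
            self._maf = np.minimum(p, 1.0 - p)
        return self._maf

    @property
    def hwe_p(self) -> np.ndarray:
        """Chi-square (1 df) goodness-of-fit p on rounded genotype counts."""
        if self._hwe_p is None:
            hard = np.clip(np.rint(self.dosages), 0, 2).astype(int)
            n = hard.shape[0]
            n_aa = (hard == 0).sum(axis=0)
            n_ab = (hard == 1).sum(axis=0)
            n_bb = (hard == 2).sum(axis=0)
            p = (n_ab + 2 * n_bb) / (2.0 * n)
            q = 1.0 - p
            exp = np.stack([n * q**2, 2 * n * p * q, n * p**2])
            obs = np.stack([n_aa, n_ab, n_bb])
            with np.errstate(divide="ignore", invalid="ignore"):
                chi2 = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0).sum(axis=0)
            out = stats.chi2.sf(chi2, df=1)
            out[(p == 0) | (q == 0)] = 1.0  # monomorphic: nothing to test
            self._hwe_p = out
        return self._hwe_p

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=self.variants.loc[np.asarray(mask)].reset_index(drop=True),
            dosages=self.dosages[:, np.asarray(mask)],
        )


@dataclass
class WeightTable:
    """SNP effect weights: one row per (variant, tag) after averaging."""

    table: pd.DataFrame  # columns: variant, effect_allele, beta, tag

    def __post_init__(self) -> None:
        required = {"variant", "effect_allele", "beta", "tag"}
        if not required <= set(self.table.columns):
            raise ValueError(f"weight table needs columns {sorted(required)}")
        if not np.isfinite(self.table["beta"]).all():
            raise ValueError("non-finite beta in weight table")
        if self.table.duplicated(["variant", "tag"]).any():
            raise ValueError("duplicate (variant, tag) pairs after averaging")

    def for_tag(self, tag: str) -> pd.DataFrame:
        return self.table[self.table["tag"] == tag].reset_index(drop=True)

    @property
    def tags(self) -> list[str]:
        return list(dict.fromkeys(self.table["tag"]))


# ---------------------------------------------------------------------------
# vocabulary
# ---------------------------------------------------------------------------


def read_vocabulary(path) -> DiseaseVocabulary:
    """Parse a code -> disease-group -> category table.

    Fully duplicated rows are collapsed; a code appearing under two distinct
    groups is a hard error (group code sets must not overlap).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).drop_duplicates()
    required = {"code", "disease_group", "category"}
    if not required <= set(df.columns):
        raise ValueError(f"vocabulary needs columns {sorted(required)}")
    if df["code"].duplicated().any():
        bad = df.loc[df["code"].duplicated(), "code"].iloc[0]
        raise ValueError(f"code {bad!r} mapped to more than one disease group")
    if df["category"].isna().any() or (df["category"].str.len() == 0).any():
        raise ValueError("empty category in vocabulary")
    entries = {
        r.code: (r.disease_group, r.category) for r in df.itertuples(index=False)
    }
    groups = tuple(dict.fromkeys(df["disease_group"]))
    categories = tuple(dict.fromkeys(df["category"]))
    return DiseaseVocabulary(entries=entries, groups=groups, categories=categories)


def write_vocabulary(vocab: DiseaseVocabulary, path) -> None:
    rows = [
        {"code": c, "disease_group": g, "category": cat}
        for c, (g, cat) in vocab.entries.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# diagnosis histories
# ---------------------------------------------------------------------------


def read_histories(path, vocab: DiseaseVocabulary) -> DiagnosisCorpus:
    """Parse per-patient diagnosis events and translate codes to groups.

    Events are sorted by date per patient (same-day events keep file order);
    codes absent from the vocabulary are dropped and tallied.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"patient_id", "date", "code"}
    if not required <= set(df.columns):
        raise ValueError(f"histories need columns {sorted(required)}")
    try:
        parsed = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError):
        # re-parse row by row to name the offending line
        for i, v in enumerate(df["date"]):
            try:
                pd.to_datetime(v, format="ISO8601")
            except (ValueError, TypeError):
                raise ValueError(f"unparsable date {v!r} at data line {i + 1}")
        raise
    df = df.assign(_date=parsed.dt.date, _row=np.arange(len(df)))

    known = df["code"].isin(vocab.entries)
    n_unknown = int((~known).sum())
    if n_unknown:
        logger.warning("dropped %d events with codes not in vocabulary", n_unknown)
    df = df[known]

    corpus = DiagnosisCorpus(n_unknown_codes=n_unknown)
    for pid, sub in df.groupby("patient_id", sort=False):
        sub = sub.sort_values(["_date", "_row"], kind="stable")
        events = tuple(
            (d, vocab.group_of(c)) for d, c in zip(sub["_date"], sub["code"])
        )
        corpus.histories[pid] = DiagnosisHistory(patient_id=pid, events=events)
    return corpus


def write_histories(corpus: DiagnosisCorpus, vocab: DiseaseVocabulary, path) -> None:
    """Serialize a corpus using one representative code per disease group."""
    code_of = {}
    for code, (group, _) in vocab.entries.items():
        code_of.setdefault(group, code)
    rows = [
        {"patient_id": h.patient_id, "date": d.isoformat(), "code": code_of[t]}
        for h in corpus
        for d, t in h.events
    ]
    pd.DataFrame(rows, columns=["patient_id", "date", "code"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _impute_missing(dos: np.ndarray) -> np.ndarray:
    """Replace NaN dosages with the per-variant mean of observed dosages."""
    miss = np.isnan(dos)
    if miss.any():
        logger.warning("imputed %d missing genotypes to variant means", miss.sum())
        col_mean = np.nanmean(np.where(miss, np.nan, dos), axis=0)
        col_mean = np.nan_to_num(col_mean)  # all-missing variant -> 0
        dos = np.where(miss, col_mean[None, :], dos)
    return dos


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, eas, oas, cols = [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"variant {var.ID} is not biallelic")
        fmts = var.FORMAT
        if "DS" in fmts:
            d = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        else:
            gt = var.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            d = np.select(
                [gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan
            )
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        eas.append(var.ALT[0])
        oas.append(var.REF)
        cols.append(d)
    dos = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    if dos.size and np.nanmax(dos) > 2 + 1e-9:
        raise ValueError("dosage outside [0, 2] in VCF")
    dos = _impute_missing(dos)
    variants = pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": poss, "ea": eas, "oa": oas}
    )
    return GenotypeMatrix(sample_ids=samples, variants=variants, dosages=dos)


def _read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "sample_id":
        raise ValueError("dosage TSV must start with a sample_id column")
    samples = df["sample_id"].astype(str).tolist()
    meta = []
    for col in df.columns[1:]:
        parts = col.split(":")
        if len(parts) != 5:
            raise ValueError(f"variant column {col!r} is not id:chrom:pos:ea:oa")
        meta.append(
            {
                "id": parts[0],
                "chrom": parts[1],
                "pos": int(parts[2]),
                "ea": parts[3],
                "oa": parts[4],
            }
        )
    dos = df.iloc[:, 1:].to_numpy(dtype=float)
    if dos.size and (np.nanmin(dos) < -1e-9 or np.nanmax(dos) > 2 + 1e-9):
        raise ValueError("dosage outside [0, 2] in TSV")
    dos = _impute_missing(dos)
    return GenotypeMatrix(
        sample_ids=samples, variants=pd.DataFrame(meta), dosages=dos
    )


def read_dosages(path, format: str = "tsv") -> GenotypeMatrix:
    """Read genotypes from an uncompressed VCF (``vcf``) or dosage TSV."""
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_dosages_tsv(G: GenotypeMatrix, path) -> None:
    cols = {
        f"{r.id}:{r.chrom}:{r.pos}:{r.ea}:{r.oa}": G.dosages[:, i]
        for i, r in enumerate(G.variants.itertuples(index=False))
    }
    out = pd.DataFrame({"sample_id": G.sample_ids, **cols})
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# SNP weights
# ---------------------------------------------------------------------------


def read_weights(path) -> WeightTable:
    """Read SNP weights; duplicate (variant, tag) rows are mean-averaged."""
    df = pd.read_csv(path, sep="\t", dtype={"variant": str, "tag": str})
    required = {"variant", "effect_allele", "beta", "tag"}
    if not required <= set(df.columns):
        raise ValueError(f"weights need columns {sorted(required)}")
    beta = pd.to_numeric(df["beta"], errors="coerce")
    if beta.isna().any():
        bad = df.loc[beta.isna(), "beta"].iloc[0]
        raise ValueError(f"non-numeric beta {bad!r} in weight table")
    df = df.assign(beta=beta)
    collapsed = (
        df.groupby(["variant", "tag"], sort=False, as_index=False)
        .agg(effect_allele=("effect_allele", "first"), beta=("beta", "mean"))
    )[["variant", "effect_allele", "beta", "tag"]]
    return WeightTable(table=collapsed)


def write_weights(W: WeightTable, path) -> None:
    W.table.to_csv(path, sep="\t", index=False, float_format="%.17g")
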