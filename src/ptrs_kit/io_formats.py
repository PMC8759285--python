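"""Readers/writers for genotypes, weight models, phenotype tables and scores.

Genotypes are accepted as VCF 4.x (``DS`` preferred, ``GT`` fallback) or as a
native tab-delimited dosage table with header
``variant_id chrom pos ref effect <sample> ...`` and one row per variant.
Expression prediction weights are accepted as TSV with columns
``gene variant_id effect_allele other_allele weight`` (the layout of
predictdb-style weight tables) or as an SQLite database with a ``weights``
table of the same columns.

Allele harmonization between a weight store and a genotype panel matches on
``variant_id`` and reconciles allele encodings: swapped effect/other alleles
negate the weight; non-palindromic strand complements are accepted; A/T and
C/G (palindromic) variants whose alleles do not match directly are dropped
rather than guessed.
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "effect"]
WEIGHT_COLUMNS = ["gene", "variant_id", "effect_allele", "other_allele", "weight"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SchemaError(ValueError):
    """A required column or field is missing or malformed."""


class GenotypeDataError(ValueError):
    """A genotype record violates the dosage contract."""


def _complement(allele: str) -> str | None:
    try:
        return "".join(_COMPLEMENT[b] for b in allele)
    except KeyError:
        return None


def _is_palindromic(a1: str, a2: str) -> bool:
    return _complement(a1) == a2


@dataclass
class GenotypeMatrix:
    """Individuals × variants effect-allele dosage matrix with variant metadata.

    Parameters
    ----------
    sample_ids
        Ordered sample identifiers (rows of ``dosages``).
    variants
        DataFrame with columns ``variant_id, chrom, pos, ref, effect``;
        positions are 1-based and must be non-decreasing within a chromosome.
    dosages
        ``(n_samples, n_variants)`` float array; entries in ``[0, 2]`` or NaN
        for missing.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise SchemaError(f"variant table missing columns: {missing}")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if self.variants["variant_id"].duplicated().any():
            dup = self.variants.loc[self.variants["variant_id"].duplicated(), "variant_id"]
            raise ValueError(f"duplicate variant ids: {sorted(set(dup))[:5]}")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeDataError(
                f"dosage out of [0, 2] at sample {self.sample_ids[i]!r}, "
                f"variant {self.variants['variant_id'].iloc[j]!r}: {self.dosages[i, j]}"
            )
        for _, grp in self.variants.groupby("chrom", sort=False):
            if (np.diff(grp["pos"].to_numpy()) < 0).any():
                raise ValueError(f"positions not sorted within chromosome {_!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def mean_imputed(self) -> np.ndarray:
        """Dosages with per-variant mean imputation of missing entries."""
        d = self.dosages.copy()
        if np.isnan(d).any():
            col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(np.isnan(d))
            d[idx] = col_mean[idx[1]]
        return d

    def standardized(self) -> tuple[np.ndarray, np.ndarray]:
        """Column-standardized mean-imputed dosages.

        Returns ``(matrix, kept)`` where ``kept`` indexes the variants with
        nonzero variance (zero-variance variants are dropped and logged).
        """
        d = self.mean_imputed()
        sd = d.std(axis=0, ddof=1)
        kept = np.flatnonzero(sd > 0)
        if len(kept) < d.shape[1]:
            log.warning("dropping %d zero-variance variants", d.shape[1] - len(kept))
        d = d[:, kept]
        return (d - d.mean(axis=0)) / d.std(axis=0, ddof=1), kept

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        """Row subset in the given order (all ids must be present)."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ValueError(f"samples absent from genotypes: {missing[:5]}")
        rows = [index[s] for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), self.variants.copy(), self.dosages[rows])

    def allele_frequencies(self) -> np.ndarray:
        """Per-variant effect-allele frequency from mean dosage."""
        return np.nanmean(self.dosages, axis=0) / 2.0


@dataclass
class WeightModelStore:
    """Per-gene sparse variant→weight maps with effect alleles.

    ``table`` has columns ``gene, variant_id, effect_allele, other_allele,
    weight`` (plus an optional ``flipped`` marker added by harmonization);
    ``metadata`` carries free-form tags such as tissue and training population.
    """

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in WEIGHT_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"weight table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        if self.table.duplicated(subset=["gene", "variant_id"]).any():
            dup = self.table.loc[
                self.table.duplicated(subset=["gene", "variant_id"]), ["gene", "variant_id"]
            ]
            raise ValueError(f"duplicate (gene, variant) pairs: {dup.values[:3].tolist()}")
        if len(self.table) and not np.isfinite(self.table["weight"].to_numpy(float)).all():
            raise ValueError("non-finite weight values in weight table")

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.table["gene"]))

    @property
    def n_genes(self) -> int:
        return self.table["gene"].nunique()

    def weights_for(self, gene: str) -> pd.DataFrame:
        return self.table[self.table["gene"] == gene]


@dataclass
class PhenotypeTable:
    """Traits and covariates keyed by sample id; rows with missing values excluded."""

    table: pd.DataFrame  # indexed by sample_id
    trait_cols: list[str]
    covariate_cols: list[str]

    def __post_init__(self) -> None:
        for c in self.trait_cols + self.covariate_cols:
            if c not in self.table.columns:
                raise SchemaError(f"phenotype table missing column {c!r}")
        n0 = len(self.table)
        self.table = self.table.dropna(subset=self.trait_cols + self.covariate_cols)
        if len(self.table) < n0:
            log.info("excluded %d individuals with missing phenotype/covariate", n0 - len(self.table))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index.astype(str))

    def aligned_to(self, sample_ids: list[str]) -> "PhenotypeTable":
        """Subset and reorder to ``sample_ids`` (all must be present)."""
        missing = set(sample_ids) - set(self.sample_ids)
        if missing:
            raise ValueError(f"samples absent from phenotype table: {sorted(missing)[:5]}")
        return PhenotypeTable(self.table.loc[sample_ids], self.trait_cols, self.covariate_cols)

    def covariates(self) -> np.ndarray:
        return self.table[self.covariate_cols].to_numpy(float)

    def trait(self, name: str) -> np.ndarray:
        if name not in self.trait_cols:
            raise KeyError(f"unknown trait {name!r}; available: {self.trait_cols}")
        return self.table[name].to_numpy(float)


# ---------------------------------------------------------------------------
# genotype IO


def _parse_region(region: str) -> tuple[str, int, int]:
    chrom, _, span = region.partition(":")
    if span:
        lo, _, hi = span.partition("-")
        return chrom, int(lo), int(hi)
    return chrom, 1, 2**62


def read_genotypes(path: str | Path, region: str | None = None) -> GenotypeMatrix:
    """Read a VCF (``.vcf``/``.vcf.gz``) or native dosage TSV into a GenotypeMatrix.

    For VCF input, the ``DS`` FORMAT field is used when present; otherwise the
    dosage is the count of ALT alleles in ``GT`` (missing calls → NaN).
    Multi-allelic records are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if ".vcf" in path.suffixes or path.suffix == ".vcf" or str(path).endswith(".vcf.gz"):
        return _read_vcf(path, region)
    return _read_dosage_tsv(path, region)


def _read_vcf(path: Path, region: str | None) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    want = _parse_region(region) if region else None
    rows, dosage_rows = [], []
    for rec in vcf:
        if want is not None:
            chrom, lo, hi = want
            if rec.CHROM != chrom or not (lo <= rec.POS <= hi):
                continue
        if len(rec.ALT) != 1:
            log.warning("dropping multi-allelic record %s:%d", rec.CHROM, rec.POS)
            continue
        ds = None
        try:
            ds = rec.format("DS")
        except Exception:
            ds = None
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(-1)
        elif rec.genotypes is not None and len(rec.genotypes):
            dose = np.empty(len(samples))
            for i, gt in enumerate(rec.genotypes):
                alleles = gt[:-1]
                if any(a < 0 for a in alleles):
                    dose[i] = np.nan
                else:
                    dose[i] = float(sum(1 for a in alleles if a > 0))
        else:
            raise SchemaError(
                f"record {rec.CHROM}:{rec.POS} has neither DS nor GT; unsupported format"
            )
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        with np.errstate(invalid="ignore"):
            if ((dose < 0) | (dose > 2)).any():
                raise GenotypeDataError(
                    f"dosage out of [0, 2] in record {rec.CHROM}:{rec.POS} ({vid})"
                )
        rows.append((vid, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        dosage_rows.append(dose)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosages = np.array(dosage_rows, dtype=float).reshape(len(rows), len(samples)).T
    return GenotypeMatrix(samples, variants, dosages)


def _read_dosage_tsv(path: Path, region: str | None) -> GenotypeMatrix:
    try:
        df = pd.read_csv(
            path, sep="\t", dtype={"variant_id": str, "chrom": str},
            float_precision="round_trip",
        )
    except Exception as exc:  # noqa: BLE001
        raise SchemaError(f"cannot parse dosage table {path}: {exc}") from exc
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"dosage table {path} missing columns: {missing}")
    if region:
        chrom, lo, hi = _parse_region(region)
        df = df[(df["chrom"] == chrom) & (df["pos"] >= lo) & (df["pos"] <= hi)]
    samples = [c for c in df.columns if c not in VARIANT_COLUMNS]
    dosages = df[samples].to_numpy(float).T
    return GenotypeMatrix(samples, df[VARIANT_COLUMNS], dosages)


def write_genotypes(G: GenotypeMatrix, path: str | Path) -> None:
    """Write the native dosage TSV dialect (bit-exact float round trip)."""
    df = pd.concat(
        [G.variants, pd.DataFrame(G.dosages.T, columns=G.sample_ids, index=G.variants.index)],
        axis=1,
    )
    with open(path, "w") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join("" if _isnan(v) else _fmt(v) for v in row) + "\n")


def _isnan(v) -> bool:
    return isinstance(v, float) and np.isnan(v)


def _fmt(v) -> str:
    return repr(float(v)) if isinstance(v, float) else str(v)


# ---------------------------------------------------------------------------
# weight model IO


def read_weight_models(path: str | Path, metadata: dict | None = None) -> WeightModelStore:
    """Read a weight store from TSV or SQLite (``weights`` table)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in {".db", ".sqlite", ".sqlite3"}:
        with sqlite3.connect(path) as conn:
            df = pd.read_sql_query("SELECT * FROM weights", conn)
    else:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.empty and not set(WEIGHT_COLUMNS) <= set(df.columns):
        log.warning("empty weight file %s: returning empty store", path)
        df = pd.DataFrame(columns=WEIGHT_COLUMNS)
    missing = [c for c in WEIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"weight table {path} missing columns: {missing}")
    if df["weight"].isna().any():
        bad = df.index[df["weight"].isna()][0]
        raise ValueError(f"unparseable weight at row {bad} of {path}")
    if df.empty:
        log.warning("weight file %s contains no entries", path)
    return WeightModelStore(df[WEIGHT_COLUMNS].copy(), metadata or {})


def write_weight_models(store: WeightModelStore, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in {".db", ".sqlite", ".sqlite3"}:
        with sqlite3.connect(path) as conn:
            store.table.to_sql("weights", conn, index=False, if_exists="replace")
    else:
        store.table.to_csv(path, sep="\t", index=False)


def harmonize_alleles(G: GenotypeMatrix, W: WeightModelStore) -> WeightModelStore:
    """Reconcile weight-model alleles with genotype alleles (lossy, logged).

    For each model variant present in ``G``: a direct allele match keeps the
    weight; swapped effect/other alleles negate it (flip recorded); anything
    else (absent variant, incompatible alleles) is dropped.  Palindromic
    (A/T, C/G) model variants are dropped outright — a strand flip cannot be
    distinguished from an allele swap for them, and we do not guess.
    Genes losing all their variants are dropped with a warning.
    Idempotent: a harmonized store passes through unchanged.
    """
    geno = G.variants.set_index("variant_id")
    rows = []
    n_flip = n_drop = 0
    for rec in W.table.itertuples(index=False):
        if rec.variant_id not in geno.index:
            n_drop += 1
            continue
        ref, eff = geno.loc[rec.variant_id, ["ref", "effect"]]
        ea, oa = str(rec.effect_allele), str(rec.other_allele)
        if _is_palindromic(ea, oa):
            log.info("dropping strand-ambiguous variant %s (%s/%s)", rec.variant_id, ea, oa)
            n_drop += 1
            continue
        if (ea, oa) == (eff, ref):
            rows.append((rec.gene, rec.variant_id, eff, ref, rec.weight, False))
        elif (ea, oa) == (ref, eff):
            rows.append((rec.gene, rec.variant_id, eff, ref, -rec.weight, True))
            n_flip += 1
        else:
            n_drop += 1
    out = pd.DataFrame(rows, columns=WEIGHT_COLUMNS + ["flipped"])
    lost = set(W.table["gene"]) - set(out["gene"])
    if lost:
        log.warning("harmonization dropped %d genes with no usable variants", len(lost))
    if n_flip or n_drop:
        log.info("harmonization: %d weights flipped, %d variants dropped", n_flip, n_drop)
    return WeightModelStore(out, dict(W.metadata))


# ---------------------------------------------------------------------------
# phenotype / score IO


def read_phenotypes(
    path: str | Path, trait_cols: list[str], covariate_cols: list[str]
) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise SchemaError(f"phenotype table {path} missing 'sample_id' column")
    return PhenotypeTable(df.set_index("sample_id"), trait_cols, covariate_cols)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.table.rename_axis("sample_id").reset_index().to_csv(path, sep="\t", index=False)


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    """Write per-sample scores (columns = hyperparameters) in long TSV form."""
    long = scores.rename_axis("sample_id").reset_index().melt(
        id_vars="sample_id", var_name="hyperparameter", value_name="score"
    )
    long[["sample_id", "score", "hyperparameter"]].to_csv(path, sep="\t", index=False)
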