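"""Predicted transcriptome: imputation from dosages, normalization, eigenfeatures.

Predicted expression of gene g in individual i is the weighted dosage sum
T̂_ig = Σ_j X_ij w_gj over the gene's cis variants.  Two normalizations are
used downstream: per-column standardization (mean 0, sd 1; used when fitting
and applying score models) and rank-based inverse normalization
T̃ = Φ⁻¹(rank/(N+1)) (used for variance-component PVE, where the mixed model
assumes N(0,1) features).

For multi-tissue analyses, per-gene cross-tissue matrices are compressed to
left singular vectors ("eigenfeatures"), retaining components whose singular
value is at least ``retain_ratio`` (default 1/30) of the gene's largest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse, stats

from .io_formats import GenotypeMatrix, WeightModelStore

log = logging.getLogger(__name__)


@dataclass
class PredictedExpression:
    """Individuals × features matrix of genetically predicted expression.

    ``state`` is one of ``raw``, ``standardized``, ``inverse_normalized``.
    Feature ids are gene ids, or ``gene#k`` for multi-tissue eigenfeatures.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    state: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("values shape does not match sample/feature ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def column(self, feature: str) -> np.ndarray:
        return self.values[:, self.feature_ids.index(feature)]


def predict_expression(G: GenotypeMatrix, W: WeightModelStore) -> PredictedExpression:
    """Impute expression: value(i, g) = Σ_j dosage(i, j) · w(g, j).

    ``W`` must already be harmonized to ``G``.  Missing dosages are
    mean-imputed per variant.  Genes with no usable variant are absent from
    the output; if no gene has any, an error lists the missing genes.
    """
    genes = W.genes
    vindex = {v: k for k, v in enumerate(G.variants["variant_id"])}
    tab = W.table[W.table["variant_id"].isin(vindex)]
    usable_genes = [g for g in genes if g in set(tab["gene"])]
    if not usable_genes:
        raise ValueError(f"no weight-model variants found in genotypes; missing genes: {genes[:10]}")
    dropped = [g for g in genes if g not in set(tab["gene"])]
    if dropped:
        log.warning("dropping %d genes with no variants in the genotype panel", len(dropped))
    gidx = {g: k for k, g in enumerate(usable_genes)}
    rows = tab["variant_id"].map(vindex).to_numpy()
    cols = tab["gene"].map(gidx).to_numpy()
    wmat = sparse.coo_matrix(
        (tab["weight"].to_numpy(float), (rows, cols)), shape=(G.n_variants, len(usable_genes))
    ).tocsc()
    values = G.mean_imputed() @ wmat
    values = np.asarray(values)
    degenerate = np.flatnonzero(np.abs(values).max(axis=0) == 0)
    if len(degenerate):
        log.warning(
            "degenerate (all-zero) predicted expression for genes: %s",
            [usable_genes[k] for k in degenerate[:10]],
        )
    return PredictedExpression(list(G.sample_ids), usable_genes, values, "raw")


def standardize(T: PredictedExpression) -> PredictedExpression:
    """Column-standardize (mean 0, sd 1 with ddof=1) within the given cohort.

    Zero-variance columns are dropped with a warning.  Idempotent on already
    standardized input.
    """
    if T.n_samples < 2:
        raise ValueError("standardization requires at least 2 samples")
    sd = T.values.std(axis=0, ddof=1)
    keep = np.flatnonzero(sd > 0)
    if len(keep) < T.n_features:
        log.warning("standardize: dropping %d constant features", T.n_features - len(keep))
    vals = T.values[:, keep]
    vals = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=1)
    return PredictedExpression(
        T.sample_ids, [T.feature_ids[k] for k in keep], vals, "standardized"
    )


def inverse_normalize(T: PredictedExpression) -> PredictedExpression:
    """Rank-based inverse normal transform: T̃ = Φ⁻¹(rank/(N+1)), average ties."""
    if T.n_samples < 2:
        raise ValueError("inverse normalization requires at least 2 samples")
    n = T.n_samples
    ranks = np.apply_along_axis(stats.rankdata, 0, T.values)  # average ties
    vals = stats.norm.ppf(ranks / (n + 1))
    return PredictedExpression(T.sample_ids, list(T.feature_ids), vals, "inverse_normalized")


def multi_tissue_features(
    T_list: list[PredictedExpression], retain_ratio: float = 1.0 / 30.0
) -> PredictedExpression:
    """Compress per-gene cross-tissue expression into orthonormal eigenfeatures.

    For each gene, the N×K matrix of its predicted expression across the K
    tissues where it is available is column-centered and decomposed by SVD;
    left singular vectors with singular value ≥ ``retain_ratio`` × the gene's
    maximum are kept, named ``gene#1..``.  Genes present in no tissue are
    skipped.
    """
    if not T_list:
        raise ValueError("no tissues given")
    samples = T_list[0].sample_ids
    for t in T_list[1:]:
        if t.sample_ids != samples:
            raise ValueError("all tissues must share the same sample ordering")
    genes: list[str] = list(dict.fromkeys(g for t in T_list for g in t.feature_ids))
    out_cols, out_names = [], []
    for g in genes:
        cols = [t.column(g) for t in T_list if g in t.feature_ids]
        mat = np.column_stack(cols)
        mat = mat - mat.mean(axis=0)
        u, s, _ = np.linalg.svd(mat, full_matrices=False)
        if s[0] <= 0:
            continue  # constant across samples in every tissue
        keep = np.flatnonzero(s >= retain_ratio * s[0])
        for k in keep:
            out_cols.append(u[:, k])
            out_names.append(f"{g}#{k + 1}")
    if not out_names:
        raise ValueError("no non-degenerate genes across tissues")
    return PredictedExpression(list(samples), out_names, np.column_stack(out_cols), "raw")
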