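"""Two-population synthetic cohorts with expression-mediated traits.

Genotypes follow a Balding–Nichols model: ancestral allele frequencies are
Uniform(0.05, 0.95) and each population's frequency is a Beta draw around the
ancestral one with divergence parameter F (variance F·p·(1−p)); dosages are
Binomial(2, p_pop), optionally with local LD induced by an AR(1) Gaussian
copula over adjacent variants on each haplotype.

Each gene is assigned a block of consecutive cis variants with N(0, 1)
weights (the "expression model"); the trait is

    Y = Σ_l C_l a_l + Σ_g T̃_g β_g + Σ_j X_j b_j + ε,

with T̃ the inverse-normalized predicted expression, β_g ~ N(0, σ_g²/M),
sparse direct variant effects b, and Gaussian noise.  The mediated, direct
and noise components are rescaled so their realized variance fractions of
the non-covariate variance equal ``mediated_h2``, ``direct_h2`` and the
remainder exactly.  Covariates are age, sex, age², sex×age, sex×age² and the
top genotype PCs of the pooled cohort.  Everything is deterministic under
``seed``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix, PhenotypeTable, WeightModelStore, WEIGHT_COLUMNS
from .transcriptome import inverse_normalize, predict_expression

log = logging.getLogger(__name__)

_ALLELES = ("A", "C", "G", "T")

COVARIATE_BASE = ["age", "sex", "age2", "sex_age", "sex_age2"]


@dataclass
class SimConfig:
    """Study conditions of the synthetic two-population cohort."""

    n_per_population: int = 1000
    n_variants: int = 500
    n_genes: int = 100
    cis_variants_per_gene: int = 3
    fst_like_divergence: float = 0.1
    mediated_h2: float = 0.3
    direct_h2: float = 0.2
    #: correlation between the two populations' direct variant effects
    direct_effect_correlation: float = 1.0
    n_causal_variants: int = 50
    covariate_effect_sd: float = 0.3
    #: adjacent-variant haplotype correlation (AR(1) Gaussian copula); 0 = LE
    ld_rho: float = 0.0
    n_genotype_pcs: int = 5
    variant_spacing_bp: int = 5000
    population_labels: tuple[str, ...] = ("pop1", "pop2")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mediated_h2 + self.direct_h2 > 1 + 1e-12:
            raise ValueError("mediated_h2 + direct_h2 must be <= 1")
        for name in ("n_per_population", "n_variants", "n_genes", "cis_variants_per_gene"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.fst_like_divergence < 1):
            raise ValueError("fst_like_divergence must be in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    gene_effects: pd.Series  # beta_g used for the mediated component (post-scaling)
    variant_effects: dict[str, pd.Series]  # per population, post-scaling
    allele_freqs: pd.DataFrame  # index variant_id, one column per population + ancestral
    realized_fractions: dict[str, dict[str, float]]  # per population
    config: SimConfig = field(repr=False, default=None)


def _rng(cfg: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, salt]))


def simulate_genotypes(cfg: SimConfig) -> tuple[dict[str, GenotypeMatrix], SimTruth]:
    """Draw per-population dosage matrices under the Balding–Nichols model."""
    rng = _rng(cfg, 1)
    p_anc = rng.uniform(0.05, 0.95, cfg.n_variants)
    f = cfg.fst_like_divergence
    freqs = {"ancestral": p_anc}
    genos: dict[str, GenotypeMatrix] = {}
    vids = [f"var{j}" for j in range(cfg.n_variants)]
    pos = 1 + np.arange(cfg.n_variants) * cfg.variant_spacing_bp
    # avoid palindromic (strand-ambiguous) ref/effect pairs
    _pairs = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T"), ("C", "A"), ("G", "A")]
    pick = rng.integers(0, len(_pairs), cfg.n_variants)
    ref = [_pairs[k][0] for k in pick]
    eff = [_pairs[k][1] for k in pick]
    variants = pd.DataFrame(
        {"variant_id": vids, "chrom": "1", "pos": pos, "ref": ref, "effect": eff}
    )
    for pop in cfg.population_labels:
        if f > 0:
            a = p_anc * (1 - f) / f
            b = (1 - p_anc) * (1 - f) / f
            p_pop = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)
        else:
            p_pop = p_anc.copy()
        freqs[pop] = p_pop
        n = cfg.n_per_population
        if cfg.ld_rho > 0:
            dos = np.zeros((n, cfg.n_variants))
            thresh = stats.norm.ppf(p_pop)  # P(z < thresh) = p
            for _hap in range(2):
                z = np.empty((n, cfg.n_variants))
                z[:, 0] = rng.standard_normal(n)
                innov = rng.standard_normal((n, cfg.n_variants - 1))
                r = cfg.ld_rho
                for j in range(1, cfg.n_variants):
                    z[:, j] = r * z[:, j - 1] + np.sqrt(1 - r**2) * innov[:, j - 1]
                dos += (z < thresh).astype(float)
        else:
            dos = rng.binomial(2, p_pop, size=(n, cfg.n_variants)).astype(float)
        samples = [f"{pop}_{i}" for i in range(n)]
        genos[pop] = GenotypeMatrix(samples, variants.copy(), dos)
    truth = SimTruth(
        gene_effects=pd.Series(dtype=float),
        variant_effects={},
        allele_freqs=pd.DataFrame(freqs, index=vids),
        realized_fractions={},
        config=cfg,
    )
    return genos, truth


def _gene_starts(cfg: SimConfig) -> np.ndarray:
    span = cfg.n_variants - cfg.cis_variants_per_gene
    if span < 0:
        raise ValueError("cis_variants_per_gene exceeds n_variants")
    if cfg.n_genes == 1:
        return np.array([0])
    return np.floor(np.linspace(0, span, cfg.n_genes)).astype(int)


def simulate_weight_models(cfg: SimConfig, truth: SimTruth) -> WeightModelStore:
    """Sparse cis expression models: consecutive variant blocks, N(0,1) weights."""
    rng = _rng(cfg, 2)
    starts = _gene_starts(cfg)
    vids = list(truth.allele_freqs.index)
    rows = []
    # allele metadata comes from the genotype panel layout used in simulate_genotypes
    for g, start in enumerate(starts):
        for k in range(cfg.cis_variants_per_gene):
            rows.append((f"gene{g}", vids[start + k], rng.standard_normal()))
    df = pd.DataFrame(rows, columns=["gene", "variant_id", "weight"])
    return WeightModelStore(
        _with_alleles(df, truth), {"tissue": "sim_tissue", "training_population": "ancestral"}
    )


def _with_alleles(df: pd.DataFrame, truth: SimTruth) -> pd.DataFrame:
    # effect/other alleles are unknown to the weight rows; they are filled from
    # the simulated panel so harmonization is a no-op on matched data
    return df.assign(effect_allele="?", other_allele="?")[
        ["gene", "variant_id", "effect_allele", "other_allele", "weight"]
    ]


def attach_panel_alleles(store: WeightModelStore, G: GenotypeMatrix) -> WeightModelStore:
    """Fill weight-store alleles from a genotype panel (simulated stores only)."""
    meta = G.variants.set_index("variant_id")
    tab = store.table.copy()
    tab["effect_allele"] = tab["variant_id"].map(meta["effect"])
    tab["other_allele"] = tab["variant_id"].map(meta["ref"])
    return WeightModelStore(tab[WEIGHT_COLUMNS], dict(store.metadata))


def resample_weights(
    store: WeightModelStore, fraction: float, cfg: SimConfig, salt: int = 3
) -> WeightModelStore:
    """Second 'tissue'/'population' store with a fraction of genes re-drawn.

    ``fraction`` = 0 returns an identical store; 1 redraws every gene's weight
    vector independently.
    """
    rng = _rng(cfg, salt)
    genes = store.genes
    n_resample = int(np.ceil(fraction * len(genes)))
    chosen = set(rng.choice(genes, size=n_resample, replace=False)) if n_resample else set()
    tab = store.table.copy()
    mask = tab["gene"].isin(chosen)
    tab.loc[mask, "weight"] = rng.standard_normal(int(mask.sum()))
    return WeightModelStore(tab, {**store.metadata, "resampled_fraction": fraction})


def _covariates(cfg: SimConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    age = rng.uniform(40, 70, n)
    sex = rng.integers(0, 2, n).astype(float)
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "age2": age**2,
            "sex_age": sex * age,
            "sex_age2": sex * age**2,
        }
    )


def _orthogonalize(x: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    for b in basis:
        bb = float(b @ b)
        if bb > 0:
            x = x - (float(x @ b) / bb) * b
    return x


def _scale_to(x: np.ndarray, target_var: float) -> np.ndarray:
    if target_var <= 0:
        return np.zeros_like(x)
    v = x.var(ddof=0)
    if v == 0:
        log.warning("degenerate component with zero variance cannot reach target %g", target_var)
        return x
    return x * np.sqrt(target_var / v)


def simulate_traits(
    cfg: SimConfig,
    truth: SimTruth,
    genos: dict[str, GenotypeMatrix],
    W: WeightModelStore,
) -> dict[str, PhenotypeTable]:
    """Generate per-population phenotype/covariate tables and record ground truth.

    The non-covariate part of the trait has unit variance, split exactly into
    ``mediated_h2`` (through inverse-normalized predicted expression, shared
    gene effects β_g across populations), ``direct_h2`` (sparse variant
    effects with cross-population correlation ``direct_effect_correlation``)
    and noise.  Covariate effects (N(0, covariate_effect_sd²) on standardized
    columns) are added on top.  Genotype PCs of the pooled standardized
    dosages are appended as covariates but carry no generative effect.
    """
    rng = _rng(cfg, 4)
    pops = list(genos)
    m = cfg.n_genes
    beta_g = rng.standard_normal(m) / np.sqrt(m)

    causal = rng.choice(cfg.n_variants, size=min(cfg.n_causal_variants, cfg.n_variants), replace=False)
    b_shared = rng.standard_normal(len(causal))
    b_pop = {}
    rho = cfg.direct_effect_correlation
    for pop in pops:
        b_specific = rng.standard_normal(len(causal))
        b_pop[pop] = rho * b_shared + np.sqrt(max(0.0, 1 - rho**2)) * b_specific

    # pooled genotype PCs
    k_pcs = 0
    if cfg.n_genotype_pcs > 0:
        pooled = np.vstack([genos[p].mean_imputed() for p in pops])
        ps = pooled.std(axis=0, ddof=1)
        keep = ps > 0
        pooled_std = (pooled[:, keep] - pooled[:, keep].mean(axis=0)) / ps[keep]
        k_pcs = min(cfg.n_genotype_pcs, min(pooled_std.shape) - 1)
        u, s, _ = np.linalg.svd(pooled_std, full_matrices=False)
        pcs = u[:, :k_pcs] * s[:k_pcs]
    pc_cols = [f"PC{k + 1}" for k in range(k_pcs)]

    tables: dict[str, PhenotypeTable] = {}
    offset = 0
    cov_cols = COVARIATE_BASE + pc_cols
    a_l = rng.standard_normal(len(COVARIATE_BASE)) * cfg.covariate_effect_sd
    for pop in pops:
        G = genos[pop]
        n = G.n_samples
        W_h = attach_panel_alleles(W, G)
        T = inverse_normalize(predict_expression(G, W_h))
        gvec = pd.Series(beta_g, index=[f"gene{g}" for g in range(m)])
        common = [g for g in T.feature_ids if g in gvec.index]
        mediated = T.values[:, [T.feature_ids.index(g) for g in common]] @ gvec[common].to_numpy()
        D = G.mean_imputed()
        direct = D[:, causal] @ b_pop[pop]
        noise = rng.standard_normal(n)

        # orthogonalize in sample so the realized variance fractions are exact:
        # direct against mediated (cis and causal variants overlap), noise
        # against both
        mediated = mediated - mediated.mean()
        direct = _orthogonalize(direct - direct.mean(), [mediated])
        noise = _orthogonalize(noise - noise.mean(), [mediated, direct])
        mediated = _scale_to(mediated, cfg.mediated_h2)
        direct = _scale_to(direct, cfg.direct_h2)
        noise = _scale_to(noise, 1.0 - cfg.mediated_h2 - cfg.direct_h2)

        cov = _covariates(cfg, n, rng)
        cov_std = (cov - cov.mean()) / cov.std(ddof=0)
        cov_part = cov_std.to_numpy() @ a_l
        y = mediated + direct + noise + cov_part

        tab = cov.copy()
        for k, c in enumerate(pc_cols):
            tab[c] = pcs[offset : offset + n, k]
        tab["trait"] = y
        tab.index = pd.Index(G.sample_ids, name="sample_id")
        tables[pop] = PhenotypeTable(tab, ["trait"], cov_cols)

        tot = np.var(mediated + direct + noise)
        truth.realized_fractions[pop] = {
            "mediated": float(np.var(mediated) / tot),
            "direct": float(np.var(direct) / tot),
            "noise": float(np.var(noise) / tot),
        }
        # store per-population effects on the dosage scale actually used
        scale_d = (
            np.sqrt(cfg.direct_h2 / np.var(D[:, causal] @ b_pop[pop]))
            if np.var(D[:, causal] @ b_pop[pop]) > 0 and cfg.direct_h2 > 0
            else 0.0
        )
        truth.variant_effects[pop] = pd.Series(
            b_pop[pop] * scale_d, index=[f"var{j}" for j in causal]
        )
        offset += n

    med_scale = np.sqrt(cfg.mediated_h2) if cfg.mediated_h2 > 0 else 0.0
    truth.gene_effects = pd.Series(
        beta_g * med_scale, index=[f"gene{g}" for g in range(m)]
    )
    return tables


@dataclass
class Cohort:
    """A complete simulated study: genotypes, weights, phenotypes, truth."""

    config: SimConfig
    genotypes: dict[str, GenotypeMatrix]
    weights: WeightModelStore
    phenotypes: dict[str, PhenotypeTable]
    truth: SimTruth


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Run the full generator: genotypes → weight models → traits."""
    genos, truth = simulate_genotypes(cfg)
    W = simulate_weight_models(cfg, truth)
    W = attach_panel_alleles(W, genos[cfg.population_labels[0]])
    phenos = simulate_traits(cfg, truth, genos, W)
    return Cohort(cfg, genos, W, phenos, truth)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write genotypes (dosage TSV), weights (TSV), phenotypes (TSV), truth (JSON)."""
    from .io_formats import write_genotypes, write_phenotypes, write_weight_models

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for pop, G in cohort.genotypes.items():
        write_genotypes(G, out / f"genotypes_{pop}.tsv")
        write_phenotypes(cohort.phenotypes[pop], out / f"phenotypes_{pop}.tsv")
    write_weight_models(cohort.weights, out / "weights.tsv")
    truth = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cohort.config).items()
        },
        "gene_effects": cohort.truth.gene_effects.to_dict(),
        "variant_effects": {p: s.to_dict() for p, s in cohort.truth.variant_effects.items()},
        "realized_fractions": cohort.truth.realized_fractions,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
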