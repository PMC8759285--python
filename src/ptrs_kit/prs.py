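"""GWAS, variant filters, greedy LD clumping, and the p-value-threshold PRS path.

The PRS at threshold t is PRS_i^t = Σ_{j: p_j ≤ t} X_ij b̂_j over LD-clumped
variants, with b̂_j the marginal GWAS effect.  GWAS is per-variant OLS of the
trait (original scale) on [1, covariates, dosage]; the dosage term's beta,
standard error and two-sided t p-value are reported together with the minor
allele frequency and a Hardy–Weinberg equilibrium test.  Clumping traverses
variants by increasing p-value and keeps a variant unless its squared dosage
correlation with an already-kept variant within ±250 kb exceeds 0.1
(defaults mirror `--clump-p1 1 --clump-r2 0.1 --clump-kb 250`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix, PhenotypeTable
from .transcriptome import PredictedExpression

log = logging.getLogger(__name__)

#: GWAS p-value thresholds of the PRS path.
PRS_THRESHOLDS = (5e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0)


@dataclass
class ScorePath:
    """Ordered family of sparse linear scores indexed by a hyperparameter.

    ``feature_space`` is ``"variant"`` (PRS) or ``"gene"`` (PTRS);
    ``weights`` maps each hyperparameter (p-value threshold or λ) to a
    feature → weight Series.  JSON (de)serialization round-trips exactly.
    """

    feature_space: str
    hyperparameters: list[float]
    weights: dict[float, pd.Series]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.feature_space not in {"variant", "gene"}:
            raise ValueError("feature_space must be 'variant' or 'gene'")
        if set(self.hyperparameters) != set(self.weights):
            raise ValueError("hyperparameters and weight keys disagree")

    def support(self, hp: float) -> list[str]:
        w = self.weights[hp]
        return list(w.index[w != 0])

    def support_sizes(self) -> dict[float, int]:
        return {hp: int((self.weights[hp] != 0).sum()) for hp in self.hyperparameters}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_space": self.feature_space,
            "hyperparameters": self.hyperparameters,
            "weights": {
                repr(hp): {f: w for f, w in self.weights[hp].items()}
                for hp in self.hyperparameters
            },
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScorePath":
        payload = json.loads(Path(path).read_text())
        hps = [float(h) for h in payload["hyperparameters"]]
        weights = {
            float(hp): pd.Series(wd, dtype=float)
            for hp, wd in payload["weights"].items()
        }
        return cls(payload["feature_space"], hps, weights, payload.get("provenance", {}))


# ---------------------------------------------------------------------------
# marginal association engine (shared by GWAS and PrediXcan association)


def marginal_regression(
    features: np.ndarray, y: np.ndarray, C: np.ndarray | None
) -> pd.DataFrame:
    """Per-column OLS of y on [1, C, feature]; beta/se/p for the feature term.

    Vectorized over columns via the partialling-out identity: y and each
    feature are residualized on the covariate design, and the feature term's
    estimate from the simple regression of the residuals equals the full-OLS
    estimate; degrees of freedom are those of the full model.
    Zero-variance (after residualization) columns get NaN results.
    """
    y = np.asarray(y, dtype=float).reshape(-1)
    n = len(y)
    if C is None or np.size(C) == 0:
        X0 = np.ones((n, 1))
    else:
        X0 = np.column_stack([np.ones(n), np.asarray(C, dtype=float)])
    q, _ = np.linalg.qr(X0)
    y_r = y - q @ (q.T @ y)
    F = np.asarray(features, dtype=float)
    F_r = F - q @ (q.T @ F)
    ss = np.einsum("ij,ij->j", F_r, F_r)
    ok = ss > 1e-12 * n
    beta = np.full(F.shape[1], np.nan)
    se = np.full(F.shape[1], np.nan)
    pval = np.full(F.shape[1], np.nan)
    df = n - X0.shape[1] - 1
    if df <= 0:
        raise ValueError("not enough samples for the covariate design")
    xy = F_r[:, ok].T @ y_r
    b = xy / ss[ok]
    sse = float(y_r @ y_r) - b**2 * ss[ok]
    sse = np.clip(sse, 0.0, None)
    s = np.sqrt(sse / df / ss[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(s > 0, b / s, np.inf * np.sign(b))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    beta[ok], se[ok], pval[ok] = b, s, np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame({"beta": beta, "se": se, "p": pval})


def hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    """Hardy–Weinberg χ² (1 df) test on hard calls (dosages rounded to 0/1/2)."""
    calls = np.rint(np.clip(dosages, 0, 2))
    p_out = np.ones(calls.shape[1])
    for j in range(calls.shape[1]):
        c = calls[:, j]
        c = c[~np.isnan(c)]
        n = len(c)
        if n == 0:
            continue
        n2 = float((c == 2).sum())
        n1 = float((c == 1).sum())
        p_hat = (2 * n2 + n1) / (2 * n)
        if p_hat in (0.0, 1.0):
            continue  # monomorphic: trivially in equilibrium
        exp = n * np.array([(1 - p_hat) ** 2, 2 * p_hat * (1 - p_hat), p_hat**2])
        obs = np.array([n - n1 - n2, n1, n2])
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        p_out[j] = stats.chi2.sf(chi2, 1)
    return p_out


def run_gwas(
    G: GenotypeMatrix,
    pheno: PhenotypeTable,
    trait: str,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Per-variant association scan.

    Returns a DataFrame with ``variant_id, chrom, pos, beta, se, p, maf,
    hwe_p``; variants with zero dosage variance are skipped (logged).
    """
    pheno = pheno.aligned_to(list(G.sample_ids))
    y = pheno.trait(trait)
    cov_cols = pheno.covariate_cols if covariates is None else covariates
    C = pheno.table[cov_cols].to_numpy(float) if cov_cols else None
    D = G.mean_imputed()
    res = marginal_regression(D, y, C)
    eaf = D.mean(axis=0) / 2.0
    maf = np.minimum(eaf, 1.0 - eaf)
    out = pd.DataFrame(
        {
            "variant_id": G.variants["variant_id"].to_numpy(),
            "chrom": G.variants["chrom"].to_numpy(),
            "pos": G.variants["pos"].to_numpy(),
            "beta": res["beta"].to_numpy(),
            "se": res["se"].to_numpy(),
            "p": res["p"].to_numpy(),
            "maf": maf,
            "hwe_p": hwe_pvalues(G.dosages),
        }
    )
    skipped = out["beta"].isna()
    if skipped.any():
        log.info("skipped %d zero-variance variants in GWAS", int(skipped.sum()))
    return out[~skipped].reset_index(drop=True)


def filter_variants(
    assocs: pd.DataFrame, maf_min: float = 0.001, hwe_p_min: float = 1e-10
) -> pd.DataFrame:
    """Retain variants with MAF ≥ ``maf_min`` and HWE p ≥ ``hwe_p_min``."""
    keep = (assocs["maf"] >= maf_min) & (assocs["hwe_p"] >= hwe_p_min)
    log.info("variant filter retained %d / %d", int(keep.sum()), len(assocs))
    return assocs[keep].reset_index(drop=True)


def ld_clump(
    assocs: pd.DataFrame,
    G: GenotypeMatrix,
    r2_max: float = 0.1,
    window_kb: float = 250.0,
    p1: float = 1.0,
) -> list[str]:
    """Greedy p-value-ordered clumping of variants.

    Traverses variants by increasing p (ties broken by chromosome, then
    position); a variant is kept unless its squared dosage correlation with
    an already-kept variant on the same chromosome within ``window_kb`` kb
    exceeds ``r2_max``.
    """
    df = assocs[assocs["p"] <= p1]
    df = df.sort_values(["p", "chrom", "pos"], kind="mergesort")
    col = {v: j for j, v in enumerate(G.variants["variant_id"])}
    D = G.mean_imputed()
    D = D - D.mean(axis=0)
    norms = np.sqrt(np.einsum("ij,ij->j", D, D))
    window = window_kb * 1000.0
    kept_ids: list[str] = []
    kept_idx: list[int] = []
    kept_chrom: list[str] = []
    kept_pos: list[float] = []
    for rec in df.itertuples(index=False):
        j = col[rec.variant_id]
        if norms[j] == 0:
            continue
        in_window = [
            kj
            for kj, kc, kp in zip(kept_idx, kept_chrom, kept_pos)
            if kc == rec.chrom and abs(kp - rec.pos) <= window
        ]
        if in_window:
            r = (D[:, in_window].T @ D[:, j]) / (norms[in_window] * norms[j])
            if (r**2 > r2_max).any():
                continue
        kept_ids.append(rec.variant_id)
        kept_idx.append(j)
        kept_chrom.append(rec.chrom)
        kept_pos.append(rec.pos)
    log.info("clumping kept %d / %d variants", len(kept_ids), len(df))
    return kept_ids


def build_prs_path(
    assocs: pd.DataFrame,
    kept_variants: list[str],
    thresholds: tuple[float, ...] = PRS_THRESHOLDS,
    provenance: dict | None = None,
) -> ScorePath:
    """PRS weight path: at threshold t, clumped variants with p ≤ t get weight b̂."""
    sub = assocs.set_index("variant_id").loc[kept_variants]
    weights = {}
    for t in thresholds:
        sel = sub[sub["p"] <= t]
        weights[float(t)] = pd.Series(sel["beta"].to_numpy(), index=sel.index, dtype=float)
    return ScorePath("variant", [float(t) for t in thresholds], weights, provenance or {})


def score(
    target: GenotypeMatrix | PredictedExpression, path: ScorePath
) -> pd.DataFrame:
    """Apply a score path: score_i = Σ_j feature_ij · w_j per hyperparameter.

    Variant paths expect a (harmonized) :class:`GenotypeMatrix`; gene paths
    expect standardized :class:`PredictedExpression` of the target population.
    Emits a warning when more than 20% of a model's absolute weight mass has
    no matching feature in the target.
    """
    if path.feature_space == "variant":
        if not isinstance(target, GenotypeMatrix):
            raise TypeError("variant score paths require a GenotypeMatrix")
        feats = list(target.variants["variant_id"])
        mat = target.mean_imputed()
        samples = target.sample_ids
    else:
        if not isinstance(target, PredictedExpression):
            raise TypeError("gene score paths require PredictedExpression")
        if target.state != "standardized":
            raise ValueError("gene scores are computed on within-population standardized expression")
        feats = list(target.feature_ids)
        mat = target.values
        samples = target.sample_ids
    findex = {f: j for j, f in enumerate(feats)}
    out = {}
    for hp in path.hyperparameters:
        w = path.weights[hp]
        present = w.index.isin(findex)
        mass = np.abs(w.to_numpy()).sum()
        if mass > 0:
            missing_mass = np.abs(w.to_numpy()[~present]).sum() / mass
            if missing_mass > 0.2:
                log.warning(
                    "hyperparameter %r: %.0f%% of weight mass unmatched in target",
                    hp,
                    100 * missing_mass,
                )
        wk = w[present]
        if len(wk):
            cols = [findex[f] for f in wk.index]
            out[hp] = mat[:, cols] @ wk.to_numpy()
        else:
            out[hp] = np.zeros(len(samples))
    return pd.DataFrame(out, index=pd.Index(samples, name="sample_id"))
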