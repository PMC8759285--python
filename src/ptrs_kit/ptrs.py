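"""PTRS weight paths: elastic-net regularization path and clumping/thresholding.

Elastic-net route: minimize over the joint coefficient vector β (transcriptome
block then covariate block; intercept β₀ unpenalized)

    (1/N) ‖Y − Xβ − β₀‖²₂ + λα‖β‖₁ + λ(1−α)‖β‖²₂,

with X = [T̃₁..T̃_M, C₁..C_L] column-standardized.  λ_max is the smallest λ
at which the all-zero β (with β₀ = Ȳ) satisfies the KKT condition
|∇l(β)| ≤ αλ, i.e. λ_max = max_j |(2/N) X_jᵗ(Y − Ȳ)| / α, estimated on the
first 1000 individuals by default.  The λ grid has 20 log-equispaced points
from 1.5·λ_max down to λ_max/10⁴, fitted from the largest down with warm
starts; the first 11 models with a nonzero transcriptome block form the
candidate path (matching the number of PRS thresholds).

Clumping/thresholding route: per-gene PrediXcan-style association of the
trait on predicted expression with covariates, gene-based greedy clumping at
squared expression correlation < 0.1, then a 13-point p-value-threshold path
using the association betas as weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import PhenotypeTable
from .prs import ScorePath, marginal_regression
from .transcriptome import PredictedExpression

log = logging.getLogger(__name__)

#: PrediXcan p-value thresholds of the clumping/thresholding PTRS path.
PTRS_CT_THRESHOLDS = (
    1e-6, 5e-6, 1e-5, 5e-5, 1e-4, 5e-4, 1e-3, 5e-3, 0.01, 0.05, 0.1, 0.5, 1.0,
)


def lambda_max(
    Y: np.ndarray,
    X: np.ndarray,
    alpha: float = 0.1,
    n_subsample: int | None = 1000,
) -> float:
    """Smallest λ whose all-zero solution satisfies the KKT condition.

    λ_max = max_j |(2/N) X_jᵗ (Y − Ȳ)| / α on the first ``n_subsample`` rows
    (all rows if None or larger than N).  Columns of X must be standardized.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]; the l1 threshold is undefined at alpha=0")
    Y = np.asarray(Y, dtype=float).reshape(-1)
    X = np.asarray(X, dtype=float)
    if n_subsample is not None and n_subsample < len(Y):
        Y, X = Y[:n_subsample], X[:n_subsample]
    n = len(Y)
    grad = (2.0 / n) * (X.T @ (Y - Y.mean()))
    return float(np.abs(grad).max() / alpha)


def lambda_grid(
    lam_max: float, n: int = 20, top_factor: float = 1.5, bottom_divisor: float = 1e4
) -> np.ndarray:
    """Descending log-equispaced λ sequence from 1.5·λ_max to λ_max/10⁴."""
    if lam_max <= 0:
        raise ValueError("lambda_max is zero — no signal in the input (constant Y?)")
    return np.geomspace(top_factor * lam_max, lam_max / bottom_divisor, n)


@dataclass
class ElasticNetFit:
    """Elastic-net path solutions over a descending λ grid.

    ``coefs`` is (n_lambda, M+L) with the transcriptome block first
    (``n_transcriptome`` columns), followed by the covariate block;
    ``intercepts``, ``objectives``, ``n_iters`` and ``converged`` are per λ.
    """

    lambdas: np.ndarray
    alpha: float
    intercepts: np.ndarray
    coefs: np.ndarray
    objectives: np.ndarray
    n_iters: np.ndarray
    converged: np.ndarray
    n_transcriptome: int
    feature_ids: list[str]
    penalize_covariates: bool = True
    extras: dict = field(default_factory=dict)

    def transcriptome_block(self, k: int) -> np.ndarray:
        return self.coefs[k, : self.n_transcriptome]

    def nondegenerate(self) -> np.ndarray:
        """Per-λ flag: at least one nonzero transcriptome coefficient."""
        return (self.coefs[:, : self.n_transcriptome] != 0).any(axis=1)

    def summary(self) -> str:
        lines = [
            f"Elastic-net path: alpha = {self.alpha}, {len(self.lambdas)} lambdas",
            f"  features: {self.n_transcriptome} transcriptome + "
            f"{self.coefs.shape[1] - self.n_transcriptome} covariates",
            "  lambda       active  objective",
        ]
        for k, lam in enumerate(self.lambdas):
            nact = int((self.coefs[k] != 0).sum())
            lines.append(f"  {lam:<12.5g} {nact:<7d} {self.objectives[k]:.6g}")
        return "\n".join(lines)


def _objective(
    Y: np.ndarray, X: np.ndarray, beta: np.ndarray, b0: float,
    lam: float, alpha: float, pen_mask: np.ndarray,
) -> float:
    r = Y - X @ beta - b0
    bp = beta * pen_mask
    return (
        float(r @ r) / len(Y)
        + lam * alpha * float(np.abs(bp).sum())
        + lam * (1 - alpha) * float(bp @ bp)
    )


def fit_elastic_net_path(
    Y: np.ndarray,
    T: np.ndarray | PredictedExpression,
    C: np.ndarray | None,
    alpha: float = 0.1,
    grid: np.ndarray | None = None,
    penalize_covariates: bool = True,
    feature_ids: list[str] | None = None,
    batch_size: int | None = None,
    max_iter: int = 20000,
    tol: float = 1e-10,
    kkt_tol: float = 1e-6,
    seed: int = 0,
) -> ElasticNetFit:
    """Fit the elastic-net objective along a descending λ grid with warm starts.

    Solved by accelerated proximal gradient (FISTA with monotone restart):
    soft-threshold prox at step·λα, step 1/L with L the Lipschitz bound of
    the smooth part (power iteration on XᵗX plus the ridge term), and a
    backtracking guard.  The intercept is profiled exactly each iteration.
    ``penalize_covariates=False`` exempts the covariate block from both
    penalties.  Optional mini-batch gradient steps (per-epoch shuffling under
    ``seed``) are provided for large N; the final polish is always full-batch.
    """
    if isinstance(T, PredictedExpression):
        if T.state != "standardized":
            raise ValueError("elastic net expects standardized predicted expression")
        feature_ids = list(T.feature_ids)
        T = T.values
    Y = np.asarray(Y, dtype=float).reshape(-1)
    T = np.asarray(T, dtype=float)
    n, m = T.shape
    if C is None or np.size(C) == 0:
        X = T
        n_cov = 0
    else:
        C = np.asarray(C, dtype=float)
        X = np.column_stack([T, C])
        n_cov = C.shape[1]
    p = X.shape[1]
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(m)]
    names = list(feature_ids) + [f"cov{j}" for j in range(n_cov)]
    pen_mask = np.ones(p)
    if not penalize_covariates:
        pen_mask[m:] = 0.0
    if grid is None:
        grid = lambda_grid(lambda_max(Y, X, alpha))
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) > 0):
        raise ValueError("lambda grid must be descending")

    # Lipschitz bound of (2/N) X^t X via power iteration
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(p)
    v /= np.linalg.norm(v)
    for _ in range(10):
        v = X.T @ (X @ v)
        nv = np.linalg.norm(v)
        if nv == 0:
            break
        v /= nv
    lip_smooth = 2.0 * float(v @ (X.T @ (X @ v))) / n * 1.01  # small safety margin

    coefs = np.zeros((len(grid), p))
    intercepts = np.zeros(len(grid))
    objectives = np.zeros(len(grid))
    iters = np.zeros(len(grid), dtype=int)
    converged = np.zeros(len(grid), dtype=bool)

    beta = np.zeros(p)
    for k, lam in enumerate(grid):
        ridge = 2.0 * lam * (1 - alpha)
        L = lip_smooth + ridge
        step = 1.0 / L
        thresh = step * lam * alpha * pen_mask
        b0 = float(Y.mean() - (X @ beta).mean())
        obj = _objective(Y, X, beta, b0, lam, alpha, pen_mask)
        if batch_size is not None and batch_size < n:
            beta, b0 = _minibatch_epochs(
                Y, X, beta, lam, alpha, pen_mask, step, thresh, ridge, batch_size, rng
            )
            obj = _objective(Y, X, beta, b0, lam, alpha, pen_mask)
        z = beta.copy()
        t_acc = 1.0
        it = 0
        for it in range(1, max_iter + 1):
            b0z = float(Y.mean() - (X @ z).mean())
            r = Y - X @ z - b0z
            grad = -(2.0 / n) * (X.T @ r) + ridge * (z * pen_mask)
            beta_new = np.sign(z - step * grad) * np.maximum(
                np.abs(z - step * grad) - thresh, 0.0
            )
            b0_new = float(Y.mean() - (X @ beta_new).mean())
            obj_new = _objective(Y, X, beta_new, b0_new, lam, alpha, pen_mask)
            if not np.isfinite(obj_new):
                raise FloatingPointError("elastic-net objective diverged; step-size guard failed")
            if obj_new > obj:  # monotone restart: fall back to a plain PG step
                r = Y - X @ beta - b0
                grad = -(2.0 / n) * (X.T @ r) + ridge * (beta * pen_mask)
                beta_new = np.sign(beta - step * grad) * np.maximum(
                    np.abs(beta - step * grad) - thresh, 0.0
                )
                b0_new = float(Y.mean() - (X @ beta_new).mean())
                obj_new = _objective(Y, X, beta_new, b0_new, lam, alpha, pen_mask)
                t_acc = 1.0
                z = beta_new.copy()
            else:
                t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_acc**2))
                z = beta_new + ((t_acc - 1.0) / t_new) * (beta_new - beta)
                t_acc = t_new
            rel = abs(obj - obj_new) / max(abs(obj), 1e-12)
            beta, b0, obj = beta_new, b0_new, obj_new
            if rel < tol:
                # accept only with a KKT certificate at the current point
                g = -(2.0 / n) * (X.T @ (Y - X @ beta - b0)) + ridge * (beta * pen_mask)
                active = beta != 0
                viol = max(
                    np.abs(g[active] + lam * alpha * pen_mask[active] * np.sign(beta[active])).max(initial=0.0),
                    np.maximum(np.abs(g[~active]) - lam * alpha * pen_mask[~active], 0.0).max(initial=0.0),
                )
                if viol <= kkt_tol:
                    converged[k] = True
                    break
        coefs[k] = beta
        intercepts[k] = b0
        objectives[k] = obj
        iters[k] = it
        if not converged[k]:
            log.warning("lambda %.4g: max_iter reached (rel change above tol)", lam)
    return ElasticNetFit(
        lambdas=grid,
        alpha=alpha,
        intercepts=intercepts,
        coefs=coefs,
        objectives=objectives,
        n_iters=iters,
        converged=converged,
        n_transcriptome=m,
        feature_ids=names,
        penalize_covariates=penalize_covariates,
    )


def _minibatch_epochs(Y, X, beta, lam, alpha, pen_mask, step, thresh, ridge, batch_size, rng):
    """A few epochs of mini-batch proximal steps to pre-condition the full-batch solve."""
    n = len(Y)
    b0 = float(Y.mean() - (X @ beta).mean())
    for _ in range(3):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            r = Y[idx] - X[idx] @ beta - b0
            grad = -(2.0 / len(idx)) * (X[idx].T @ r) + ridge * (beta * pen_mask)
            beta = np.sign(beta - step * grad) * np.maximum(
                np.abs(beta - step * grad) - thresh, 0.0
            )
            b0 = float(Y.mean() - (X @ beta).mean())
    return beta, b0


def kkt_violation(fit: ElasticNetFit, Y: np.ndarray, T: np.ndarray, C: np.ndarray | None) -> np.ndarray:
    """Max KKT residual per λ (diagnostic; ~0 at an exact solution).

    Active coordinates must satisfy ∇_j l + 2λ(1−α)β_j + λα·sign(β_j) = 0;
    inactive ones |∇_j l| ≤ λα.
    """
    X = T if C is None or np.size(C) == 0 else np.column_stack([T, C])
    n = len(Y)
    out = np.zeros(len(fit.lambdas))
    for k, lam in enumerate(fit.lambdas):
        beta = fit.coefs[k]
        grad = -(2.0 / n) * (X.T @ (Y - X @ beta - fit.intercepts[k]))
        viol = 0.0
        for j in range(len(beta)):
            if fit.penalize_covariates or j < fit.n_transcriptome:
                if beta[j] != 0:
                    viol = max(
                        viol,
                        abs(grad[j] + 2 * lam * (1 - fit.alpha) * beta[j] + lam * fit.alpha * np.sign(beta[j])),
                    )
                else:
                    viol = max(viol, max(0.0, abs(grad[j]) - lam * fit.alpha))
            else:
                viol = max(viol, abs(grad[j]))
        out[k] = viol
    return out


def select_nondegenerate(
    fit: ElasticNetFit, k: int = 11, provenance: dict | None = None
) -> ScorePath:
    """Keep the first ``k`` models (from the largest λ down) with a nonzero
    transcriptome block, as a gene-space :class:`ScorePath`."""
    flags = fit.nondegenerate()
    kept = [i for i in range(len(fit.lambdas)) if flags[i]][:k]
    if len(kept) < k:
        log.warning("only %d non-degenerate elastic-net models available (asked %d)", len(kept), k)
    gene_ids = fit.feature_ids[: fit.n_transcriptome]
    weights = {}
    hps = []
    for i in kept:
        lam = float(fit.lambdas[i])
        block = fit.transcriptome_block(i)
        nz = np.flatnonzero(block)
        weights[lam] = pd.Series(block[nz], index=[gene_ids[j] for j in nz], dtype=float)
        hps.append(lam)
    return ScorePath("gene", hps, weights, provenance or {"method": "elastic_net"})


# ---------------------------------------------------------------------------
# clumping / thresholding route


def predixcan_assoc(
    T: PredictedExpression,
    pheno: PhenotypeTable,
    trait: str,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene association of the trait on predicted expression with covariates.

    Uses the same marginal-OLS engine as the GWAS scan, applied to expression
    columns; returns ``gene, beta, se, p`` (zero-variance genes skipped).
    """
    pheno = pheno.aligned_to(list(T.sample_ids))
    y = pheno.trait(trait)
    cov_cols = pheno.covariate_cols if covariates is None else covariates
    C = pheno.table[cov_cols].to_numpy(float) if cov_cols else None
    res = marginal_regression(T.values, y, C)
    out = pd.DataFrame(
        {"gene": T.feature_ids, "beta": res["beta"], "se": res["se"], "p": res["p"]}
    )
    skipped = out["beta"].isna()
    if skipped.any():
        log.info("skipped %d zero-variance genes in PrediXcan association", int(skipped.sum()))
    return out[~skipped].reset_index(drop=True)


def gene_clump(
    assocs: pd.DataFrame, T: PredictedExpression, r2_max: float = 0.1
) -> list[str]:
    """Greedy gene-based clumping in predicted-expression space (no window).

    Traverses genes by increasing PrediXcan p; keeps a gene iff its squared
    expression correlation with every already-kept gene is < ``r2_max``.
    """
    df = assocs.sort_values(["p", "gene"], kind="mergesort")
    col = {g: j for j, g in enumerate(T.feature_ids)}
    V = T.values - T.values.mean(axis=0)
    norms = np.sqrt(np.einsum("ij,ij->j", V, V))
    kept: list[str] = []
    kept_idx: list[int] = []
    for rec in df.itertuples(index=False):
        j = col[rec.gene]
        if norms[j] == 0:
            continue
        if kept_idx:
            r = (V[:, kept_idx].T @ V[:, j]) / (norms[kept_idx] * norms[j])
            if (r**2 >= r2_max).any():
                continue
        kept.append(rec.gene)
        kept_idx.append(j)
    log.info("gene clumping kept %d / %d genes", len(kept), len(df))
    return kept


def build_ptrs_ct_path(
    assocs: pd.DataFrame,
    kept_genes: list[str],
    thresholds: tuple[float, ...] = PTRS_CT_THRESHOLDS,
    provenance: dict | None = None,
) -> ScorePath:
    """Clumping/thresholding PTRS path: at each p-value threshold, the kept
    genes passing it enter with their PrediXcan beta as weight."""
    sub = assocs.set_index("gene").loc[kept_genes]
    weights = {}
    for t in thresholds:
        sel = sub[sub["p"] <= t]
        weights[float(t)] = pd.Series(sel["beta"].to_numpy(), index=sel.index, dtype=float)
    return ScorePath(
        "gene", [float(t) for t in thresholds], weights,
        provenance or {"method": "clumping_thresholding"},
    )
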