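"""REML variance components on a feature relatedness matrix; PVE and heritability.

The mixed model is

    y = Cα + g + ε,   g ~ N(0, σ_g² K),   ε ~ N(0, σ_e² I),

with K = F Fᵗ / M built from M column-standardized (or inverse-normalized)
features F — predicted expression for transcriptome PVE, standardized
genotypes for chip heritability.  PVE is σ̂_g² / (σ̂_g² + σ̂_e²).

Estimation is restricted maximum likelihood with a single eigendecomposition
of K: parameterize h = σ_g²/(σ_g²+σ_e²) ∈ [0, 1); for fixed h the total
variance and fixed effects have closed-form GLS solutions, so the REML
criterion is profiled over the scalar h (coarse grid, then bounded scalar
refinement).  When K is supplied with its feature factor, the rank-r
factorization makes each profile evaluation O(N·r) instead of O(N²).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .transcriptome import PredictedExpression

log = logging.getLogger(__name__)


@dataclass
class RelatednessMatrix:
    """Symmetric PSD sample × sample similarity K = F Fᵗ / M over M features."""

    sample_ids: list[str]
    K: np.ndarray
    n_features: int
    factor: np.ndarray | None = None  # F / sqrt(M), so K = factor @ factor.T

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.sample_ids)
        if self.K.shape != (n, n):
            raise ValueError("K must be n_samples x n_samples")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("K is not symmetric within tolerance 1e-10")
        if self.factor is None and n > 1:
            lam_min = linalg.eigh(self.K, eigvals_only=True, subset_by_index=[0, 0])[0]
            if lam_min < -1e-8 * np.trace(self.K) / n:
                raise ValueError(f"K is not positive semi-definite (min eigenvalue {lam_min:.3g})")


def relatedness_from_features(
    F: PredictedExpression | np.ndarray, sample_ids: list[str] | None = None
) -> RelatednessMatrix:
    """K = F Fᵗ / M from column-standardized features.

    Accepts a :class:`PredictedExpression` (standardized or inverse
    normalized) or a plain array with ``sample_ids`` given separately.
    """
    if isinstance(F, PredictedExpression):
        if F.state == "raw":
            raise ValueError("features must be standardized or inverse-normalized first")
        sample_ids = F.sample_ids
        mat = F.values
    else:
        mat = np.asarray(F, dtype=float)
        if sample_ids is None:
            sample_ids = [str(i) for i in range(mat.shape[0])]
    m = mat.shape[1]
    if m == 0:
        raise ValueError("cannot build a relatedness matrix from zero features")
    factor = mat / np.sqrt(m)
    return RelatednessMatrix(list(sample_ids), factor @ factor.T, m, factor=factor)


@dataclass
class VarianceComponents:
    """REML estimates of (σ_g², σ_e²) and the derived PVE with its standard error."""

    sigma_g2: float
    sigma_e2: float
    pve: float
    pve_se: float
    loglik: float
    n_samples: int
    n_features: int
    boundary: bool = False
    extras: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "REML variance components",
            f"  n = {self.n_samples}, features M = {self.n_features}",
            f"  sigma_g^2 = {self.sigma_g2:.6g}",
            f"  sigma_e^2 = {self.sigma_e2:.6g}",
            f"  PVE       = {self.pve:.4f} (s.e. {self.pve_se:.4f})",
            f"  logREML   = {self.loglik:.4f}",
        ]
        if self.boundary:
            lines.append("  note: estimate on the boundary of the parameter space")
        return "\n".join(lines)


def _design(C: np.ndarray | None, n: int) -> np.ndarray:
    """Fixed-effect design with an intercept; reject collinear columns."""
    if C is None or (hasattr(C, "size") and C.size == 0):
        X = np.ones((n, 1))
    else:
        C = np.atleast_2d(np.asarray(C, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X = np.column_stack([np.ones(n), C])
    rdiag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
    bad = np.flatnonzero(rdiag < 1e-10 * rdiag.max())
    if bad.size:
        raise ValueError(
            f"singular covariate design; collinear columns (0=intercept): {bad.tolist()}"
        )
    return X


class _RemlProfile:
    """Profile REML criterion over h = σ_g²/(σ_g²+σ_e²) given eigenstructure of K."""

    def __init__(self, y: np.ndarray, X: np.ndarray, K: RelatednessMatrix):
        n = len(y)
        self.n, self.p = n, X.shape[1]
        self.y, self.X = y, X
        if K.factor is not None and K.factor.shape[1] < n:
            # economy route: K = U diag(s) U^t with rank r = n_cols(factor)
            u, sv, _ = np.linalg.svd(K.factor, full_matrices=False)
            self.s = sv**2
            self.U = u
        else:
            s, u = linalg.eigh(K.K)
            s = np.clip(s, 0.0, None)
            order = np.argsort(s)[::-1]
            self.s, self.U = s[order], u[:, order]
        self.r = len(self.s)
        self.z = self.U.T @ y  # (r,)
        self.Zx = self.U.T @ X  # (r, p)
        self.yy = float(y @ y)
        self.Xy = X.T @ y
        self.XX = X.T @ X

    def criterion(self, h: float) -> tuple[float, float]:
        """Return (log REML at profiled σ², profiled σ̂²)."""
        n, p, r = self.n, self.p, self.r
        d = h * self.s + (1.0 - h)
        w = 1.0 / d
        w0 = 1.0 / (1.0 - h)
        dw = w - w0
        yWy = float(self.z**2 @ dw) + w0 * self.yy
        XWy = self.Zx.T @ (dw * self.z) + w0 * self.Xy
        XWX = self.Zx.T @ (dw[:, None] * self.Zx) + w0 * self.XX
        try:
            cf = linalg.cho_factor(XWX)
        except linalg.LinAlgError:
            return -np.inf, np.nan
        alpha = linalg.cho_solve(cf, XWy)
        quad = yWy - float(XWy @ alpha)
        if quad <= 0:
            return -np.inf, np.nan
        sigma2 = quad / (n - p)
        logdet_d = float(np.sum(np.log(d))) + (n - r) * np.log(1.0 - h)
        logdet_xwx = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        ll = -0.5 * ((n - p) * (np.log(sigma2) + 1.0) + logdet_d + logdet_xwx)
        return ll, sigma2


def reml_fit(
    y: np.ndarray,
    C: np.ndarray | None,
    K: RelatednessMatrix,
    n_grid: int = 64,
    tol: float = 1e-6,
) -> VarianceComponents:
    """Fit y = Cα + g + ε with g ~ N(0, σ_g² K) by eigen-REML.

    The criterion is profiled over h on a grid then refined by bounded scalar
    optimization (tolerance ``tol``); boundary optima (h ≈ 0 or 1) are flagged.
    The PVE standard error comes from the observed information (numerical
    curvature of the profile criterion) in the h parameterization.
    """
    y = np.asarray(y, dtype=float).reshape(-1)
    n = len(y)
    X = _design(C, n)
    if n <= X.shape[1] + 1:
        raise ValueError("need more samples than fixed effects to fit variance components")
    prof = _RemlProfile(y, X, K)

    h_hi = 1.0 - 1e-8
    grid = np.linspace(0.0, h_hi, n_grid)
    vals = np.array([prof.criterion(h)[0] for h in grid])
    k = int(np.argmax(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda h: -prof.criterion(h)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": tol},
    )
    h_hat = float(res.x)
    ll, sigma2 = prof.criterion(h_hat)
    if not np.isfinite(ll):
        raise RuntimeError("REML criterion not finite at the optimum")
    boundary = h_hat < 1e-4 or h_hat > 1.0 - 1e-4
    if boundary and prof.criterion(0.0)[0] >= ll:
        h_hat, (ll, sigma2) = 0.0, prof.criterion(0.0)

    # observed-information s.e. in h; one-sided steps at the boundary
    step = 1e-4
    h0 = min(max(h_hat, step), h_hi - step)
    f = lambda h: prof.criterion(h)[0]  # noqa: E731
    curv = (f(h0 + step) - 2.0 * f(h0) + f(h0 - step)) / step**2
    pve_se = float(1.0 / np.sqrt(-curv)) if curv < 0 else np.nan

    sigma_g2 = h_hat * sigma2
    sigma_e2 = (1.0 - h_hat) * sigma2
    if boundary:
        log.warning("REML solution at boundary: h = %.3g", h_hat)
    return VarianceComponents(
        sigma_g2=float(sigma_g2),
        sigma_e2=float(sigma_e2),
        pve=float(h_hat),
        pve_se=pve_se,
        loglik=float(ll),
        n_samples=n,
        n_features=K.n_features,
        boundary=bool(boundary),
    )


def pve_ratio(pve: VarianceComponents, h2: VarianceComponents) -> float:
    """Fraction of heritability captured by the transcriptome: PVE / chip h²."""
    if h2.pve <= 0:
        raise ZeroDivisionError("reference heritability is zero; ratio undefined")
    ratio = pve.pve / h2.pve
    if ratio > 1:
        log.warning("PVE/h2 ratio exceeds 1 (%.3f); reported as-is", ratio)
    return float(ratio)
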