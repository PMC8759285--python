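"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most transparent route available —
naive loops, explicit dense likelihoods, coordinate descent — deliberately
avoiding the code paths of the package implementation it checks.
"""

from __future__ import annotations

import numpy as np


def naive_predicted_expression(G, W) -> dict[str, np.ndarray]:
    """Per-sample double-loop dosage × weight sums, with mean imputation."""
    d = G.dosages.copy()
    for j in range(d.shape[1]):
        col = d[:, j]
        if np.isnan(col).any():
            col[np.isnan(col)] = np.nanmean(col) if not np.isnan(col).all() else 0.0
    out = {}
    vpos = {v: j for j, v in enumerate(G.variants["variant_id"])}
    for gene in W.genes:
        vals = np.zeros(len(G.sample_ids))
        found = False
        for rec in W.weights_for(gene).itertuples(index=False):
            if rec.variant_id in vpos:
                found = True
                for i in range(len(vals)):
                    vals[i] += d[i, vpos[rec.variant_id]] * rec.weight
        if found:
            out[gene] = vals
    return out


def naive_score(features: np.ndarray, feature_ids: list[str], weights) -> np.ndarray:
    """Per-sample loop over a weight Series."""
    out = np.zeros(features.shape[0])
    for i in range(features.shape[0]):
        for f, w in weights.items():
            if f in feature_ids:
                out[i] += features[i, feature_ids.index(f)] * w
    return out


def naive_gram(F: np.ndarray) -> np.ndarray:
    """Double-loop K = F Fᵗ / M."""
    n, m = F.shape
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = float(F[i] @ F[j]) / m
    return K


def en_objective(X, y, beta, b0, lam, alpha, pen_mask=None) -> float:
    if pen_mask is None:
        pen_mask = np.ones(len(beta))
    r = y - X @ beta - b0
    bp = beta * pen_mask
    return float(r @ r) / len(y) + lam * alpha * float(np.abs(bp).sum()) + lam * (
        1 - alpha
    ) * float(bp @ bp)


def cd_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float,
    pen_mask: np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 50000,
) -> tuple[np.ndarray, float]:
    """Cyclic coordinate descent on (1/N)‖y−Xβ−β₀‖² + λα‖β‖₁ + λ(1−α)‖β‖₂²."""
    n, p = X.shape
    if pen_mask is None:
        pen_mask = np.ones(p)
    beta = np.zeros(p)
    b0 = float(y.mean())
    xx = (X**2).sum(axis=0)
    r = y - b0
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            old = beta[j]
            rho = (2.0 / n) * float(X[:, j] @ r) + (2.0 / n) * xx[j] * old
            denom = (2.0 / n) * xx[j] + 2.0 * lam * (1 - alpha) * pen_mask[j]
            if denom == 0:
                continue
            if pen_mask[j]:
                bj = np.sign(rho) * max(abs(rho) - lam * alpha, 0.0) / denom
            else:
                bj = rho / denom
            if bj != old:
                r = r + X[:, j] * (old - bj)
                beta[j] = bj
                delta = max(delta, abs(bj - old))
        b0_new = float((y - X @ beta).mean())
        r = r + (b0 - b0_new)
        b0 = b0_new
        if delta < tol:
            break
    return beta, b0


def reml_loglik_explicit(y, X, K, sigma_g2, sigma_e2) -> float:
    """Dense restricted log-likelihood (constants dropped)."""
    n = len(y)
    V = sigma_g2 * K + sigma_e2 * np.eye(n)
    sign, logdet_v = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    sign2, logdet_x = np.linalg.slogdet(XtViX)
    if sign2 <= 0:
        return -np.inf
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    return -0.5 * (logdet_v + logdet_x + float(y @ P @ y))


def brute_reml_grid(y, C, K, n_coarse: int = 41, n_fine: int = 41) -> tuple[float, float, float]:
    """Maximize the explicit REML log-likelihood over a dense 2-D grid of
    (σ_g², σ_e²), with one local refinement pass.  Returns (σ̂_g², σ̂_e², pve)."""
    y = np.asarray(y, float).reshape(-1)
    n = len(y)
    X = np.ones((n, 1)) if C is None else np.column_stack([np.ones(n), C])
    vy = float(np.var(y, ddof=1))
    ag = np.linspace(0.0, 2.0 * vy, n_coarse)
    ae = np.linspace(0.01 * vy, 2.0 * vy, n_coarse)
    best = (-np.inf, 0.0, vy)
    for sg in ag:
        for se in ae:
            ll = reml_loglik_explicit(y, X, K, sg, se)
            if ll > best[0]:
                best = (ll, sg, se)
    _, sg0, se0 = best
    dg = ag[1] - ag[0]
    de = ae[1] - ae[0]
    ag = np.linspace(max(0.0, sg0 - 2 * dg), sg0 + 2 * dg, n_fine)
    ae = np.linspace(max(1e-4 * vy, se0 - 2 * de), se0 + 2 * de, n_fine)
    for sg in ag:
        for se in ae:
            ll = reml_loglik_explicit(y, X, K, sg, se)
            if ll > best[0]:
                best = (ll, sg, se)
    _, sg, se = best
    return sg, se, sg / (sg + se)


def ols_variant_stats(y, C, x) -> tuple[float, float, float]:
    """Full-design OLS of y on [1, C, x] with classical beta/se/p for x."""
    from scipy import stats as sps

    n = len(y)
    X = np.column_stack([np.ones(n), C, x]) if C is not None else np.column_stack([np.ones(n), x])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = n - X.shape[1]
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(X.T @ X)
    beta = coef[-1]
    se = float(np.sqrt(cov[-1, -1]))
    t = beta / se
    p = 2 * sps.t.sf(abs(t), df)
    return float(beta), se, float(p)
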