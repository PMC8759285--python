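"""Partial R², repeated-split hyperparameter selection, portability, combination.

Prediction accuracy is the covariate-adjusted partial R̃²: the relative SSE
reduction of adding the score ŷ to a covariate-only regression of the trait,

    R̃² = 1 − SSE_full/SSE_null = 𝒞²(y, ŷ) / (𝒞(y, y)·𝒞(ŷ, ŷ)),
    𝒞(u, v) = uᵗv − uᵗH v,

with H the hat matrix of the null design C̃ = [1, C₁..C_L].  Hyperparameters
are chosen by repeated (default 10×) 50/50 validation/test splits of the
target cohort: the hyperparameter maximizing validation R̃² is evaluated on
the test half, and the mean test R̃² is reported.  Portability of a score in
a target population is its accuracy divided by the accuracy in the reference
target set (so the reference's own portability is 1 by definition).
PRS and PTRS are combined as c₁·PRS + c₂·PTRS with coefficients calibrated
by least squares on a nested split of the validation half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def _null_q(C: np.ndarray | None, n: int) -> np.ndarray:
    """Orthonormal basis of the null design [1, C]."""
    if C is None or np.size(C) == 0:
        X = np.ones((n, 1))
    else:
        X = np.column_stack([np.ones(n), np.asarray(C, dtype=float)])
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-12 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


def partial_r2(y: np.ndarray, yhat: np.ndarray, C: np.ndarray | None = None) -> float:
    """Covariate-adjusted squared partial correlation of ŷ with y.

    Equals 1 − SSE_full/SSE_null for the regressions y ~ 1 + C (null) and
    y ~ 1 + C + ŷ (full).  If ŷ lies in the span of the null design the
    statistic is defined as 0 (degenerate; logged).
    """
    y = np.asarray(y, dtype=float).reshape(-1)
    yhat = np.asarray(yhat, dtype=float).reshape(-1)
    q = _null_q(C, len(y))
    ry = y - q @ (q.T @ y)
    rh = yhat - q @ (q.T @ yhat)
    c_yy = float(ry @ ry)
    c_hh = float(rh @ rh)
    c_yh = float(ry @ rh)
    if c_hh <= 1e-12 * max(1.0, float(yhat @ yhat)):
        if np.any(yhat != 0):
            log.warning("score lies in the span of the covariates; partial R2 defined as 0")
        else:
            log.debug("all-zero score; partial R2 defined as 0")
        return 0.0
    if c_yy <= 0:
        return 0.0
    return c_yh**2 / (c_yy * c_hh)


@dataclass
class EvalReport:
    """Accuracy of a score family on one target cohort."""

    trait: str
    family: str
    selected: list[float]
    test_r2: list[float]
    mean_r2: float
    n_repeats: int
    seeds: list[int]
    degenerate: bool = False

    def summary(self) -> str:
        lines = [
            f"{self.family} on trait {self.trait!r}: mean test partial R2 = {self.mean_r2:.4f}",
            f"  repeats: {self.n_repeats}  (seeds {self.seeds[0]}..{self.seeds[-1]})",
        ]
        for k, (hp, r2) in enumerate(zip(self.selected, self.test_r2)):
            lines.append(f"  repeat {k}: selected {hp:.4g}, test R2 {r2:.4f}")
        return "\n".join(lines)


def _split(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random equal-size split; the first part gets the extra sample when n is odd."""
    perm = rng.permutation(n)
    half = (n + 1) // 2
    return perm[:half], perm[half:]


def select_and_test(
    scores: pd.DataFrame,
    y: np.ndarray,
    C: np.ndarray | None,
    n_repeats: int = 10,
    seed: int = 0,
    support_sizes: dict[float, int] | None = None,
    trait: str = "trait",
    family: str = "score",
) -> EvalReport:
    """Repeated validation/test splitting with validation-R̃²-maximizing selection.

    ``scores`` has one column per hyperparameter.  Ties in validation R̃² are
    broken toward the smaller model support when ``support_sizes`` is given,
    else toward the earlier column.  Split seeds are ``seed + 0..n_repeats-1``.
    """
    if scores.shape[1] < 1:
        raise ValueError("need at least one hyperparameter column")
    if len(scores) < 20:
        raise ValueError("target cohort too small for split-based evaluation (need >= 20)")
    y = np.asarray(y, dtype=float).reshape(-1)
    S = scores.to_numpy(float)
    hps = list(scores.columns)
    seeds = [seed + k for k in range(n_repeats)]
    selected, test_r2 = [], []
    degenerate = bool((S == 0).all())
    for s in seeds:
        rng = np.random.default_rng(s)
        val, test = _split(len(y), rng)
        Cv = None if C is None else np.asarray(C)[val]
        Ct = None if C is None else np.asarray(C)[test]
        val_r2 = np.array([partial_r2(y[val], S[val, j], Cv) for j in range(len(hps))])
        best = val_r2.max()
        cand = [j for j in range(len(hps)) if val_r2[j] == best]
        if support_sizes is not None and len(cand) > 1:
            cand.sort(key=lambda j: support_sizes.get(float(hps[j]), np.inf))
        j = cand[0]
        selected.append(float(hps[j]))
        test_r2.append(partial_r2(y[test], S[test, j], Ct))
    return EvalReport(
        trait=trait,
        family=family,
        selected=selected,
        test_r2=test_r2,
        mean_r2=float(np.mean(test_r2)),
        n_repeats=n_repeats,
        seeds=seeds,
        degenerate=degenerate,
    )


def portability(r2_target: float, r2_reference: float) -> float:
    """Accuracy in the target set relative to the reference target set."""
    if r2_reference <= 0:
        raise ZeroDivisionError("reference partial R2 is non-positive; portability undefined")
    return float(r2_target / r2_reference)


@dataclass
class CombinedScoreSpec:
    """A calibrated c₁·PRS + c₂·PTRS combination for one split repeat."""

    prs_hyperparameter: float
    ptrs_hyperparameter: float
    c1: float
    c2: float
    seed: int
    ridge_fallback: bool = False


@dataclass
class CombineReport:
    trait: str
    specs: list[CombinedScoreSpec]
    test_r2: list[float]
    mean_r2: float

    def summary(self) -> str:
        lines = [f"combined PRS+PTRS on {self.trait!r}: mean test partial R2 = {self.mean_r2:.4f}"]
        for spec, r2 in zip(self.specs, self.test_r2):
            lines.append(
                f"  seed {spec.seed}: t={spec.prs_hyperparameter:.3g}, "
                f"lambda={spec.ptrs_hyperparameter:.3g}, "
                f"c=({spec.c1:.3g}, {spec.c2:.3g}), test R2 {r2:.4f}"
            )
        return "\n".join(lines)


def calibrate_pair(
    y_resid: np.ndarray, prs: np.ndarray, ptrs: np.ndarray
) -> tuple[float, float, bool]:
    """Least-squares (c₁, c₂) of the covariate-residualized trait on the two
    scores; ridge jitter engages when the scores are numerically collinear."""
    A = np.column_stack([prs, ptrs])
    sd = A.std(axis=0)
    fallback = False
    with np.errstate(invalid="ignore"):
        if (sd > 0).all():
            r = float(np.corrcoef(prs, ptrs)[0, 1])
            if abs(r) > 0.9999:
                fallback = True
    gram = A.T @ A
    if fallback or np.linalg.matrix_rank(gram) < 2:
        gram = gram + 1e-8 * np.trace(gram) * np.eye(2)
        fallback = True
    c = np.linalg.solve(gram, A.T @ y_resid)
    return float(c[0]), float(c[1]), fallback


def combine_scores(
    prs_scores: pd.DataFrame,
    ptrs_scores: pd.DataFrame,
    y: np.ndarray,
    C: np.ndarray | None,
    n_repeats: int = 10,
    seed: int = 0,
    trait: str = "trait",
) -> CombineReport:
    """Nested-split calibration and selection of the combined score.

    Per repeat: the target splits into validation/test halves; the validation
    half splits again into A (coefficient calibration by least squares on the
    covariate-residualized trait, per (t, λ) pair) and B (pair selection by
    partial R̃²); the winning pair with A-fitted coefficients is scored on the
    test half.
    """
    if not prs_scores.index.equals(ptrs_scores.index):
        raise ValueError("PRS and PTRS score tables must be indexed by the same samples")
    y = np.asarray(y, dtype=float).reshape(-1)
    P = prs_scores.to_numpy(float)
    T = ptrs_scores.to_numpy(float)
    t_hps = list(prs_scores.columns)
    l_hps = list(ptrs_scores.columns)
    specs, test_r2 = [], []
    for s in [seed + k for k in range(n_repeats)]:
        rng = np.random.default_rng(s)
        val, test = _split(len(y), rng)
        a_idx, b_idx = _split(len(val), rng)
        a, b = val[a_idx], val[b_idx]
        qa = _null_q(None if C is None else np.asarray(C)[a], len(a))
        ya = y[a] - qa @ (qa.T @ y[a])
        best = None
        for ti, t in enumerate(t_hps):
            for li, lam in enumerate(l_hps):
                c1, c2, fb = calibrate_pair(ya, P[a, ti], T[a, li])
                comb_b = c1 * P[b, ti] + c2 * T[b, li]
                r2b = partial_r2(y[b], comb_b, None if C is None else np.asarray(C)[b])
                if best is None or r2b > best[0]:
                    best = (r2b, float(t), float(lam), c1, c2, fb, ti, li)
        _, t, lam, c1, c2, fb, ti, li = best
        comb_test = c1 * P[test, ti] + c2 * T[test, li]
        r2 = partial_r2(y[test], comb_test, None if C is None else np.asarray(C)[test])
        specs.append(CombinedScoreSpec(t, lam, c1, c2, seed=s, ridge_fallback=fb))
        test_r2.append(r2)
    return CombineReport(trait, specs, test_r2, float(np.mean(test_r2)))


def compare_scores(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test of per-trait accuracies.

    Exact null distribution for n ≤ 25 pairs (after dropping zero
    differences), normal approximation with continuity correction otherwise.
    All-zero differences give (0, 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 5:
        raise ValueError("need at least 5 paired accuracy values")
    d = a - b
    nz = d[d != 0]
    if len(nz) == 0:
        log.warning("all paired differences are zero; p = 1")
        return 0.0, 1.0
    method = "exact" if len(nz) <= 25 else "approx"
    res = stats.wilcoxon(
        a, b, zero_method="wilcox", alternative="two-sided", method=method, correction=True
    )
    return float(res.statistic), float(res.pvalue)


def expected_r2(n: float, h2: float, n_features: float) -> float:
    """Closed-form expected prediction r² given per-feature heritability:
    r² = x/(1+x) with x = n·h²/n_features."""
    if n <= 0 or n_features <= 0 or h2 < 0:
        raise ValueError("sample size and feature count must be positive, h2 non-negative")
    x = n * h2 / n_features
    return x / (1.0 + x)
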