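"""Ancestry label QC: multivariate-normal similarity on PC coordinates.

Each population's individuals are modelled as multivariate normal in the
space of the first 10 genotype PCs; the similarity of individual i to
population k is the log density S_ik = log Pr(PC¹..PC¹⁰; μ̂_k, Σ̂_k).
Individuals with S_ik ≤ −50 in their assigned population are filtered out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DEFAULT_CUTOFF = -50.0


@dataclass
class PopulationModel:
    """Gaussian fit of one population's PC cloud."""

    label: str
    mean: np.ndarray
    cov: np.ndarray
    ridge_applied: bool = False

    @property
    def n_pcs(self) -> int:
        return len(self.mean)


def fit_population_model(pcs: np.ndarray, label: str = "pop") -> PopulationModel:
    """Sample mean/covariance in PC space, with a ridge guard for singular fits."""
    pcs = np.asarray(pcs, dtype=float)
    n, d = pcs.shape
    if n <= d:
        raise ValueError(f"need more than {d} individuals to fit a {d}-PC model (got {n})")
    mean = pcs.mean(axis=0)
    cov = np.cov(pcs, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    ridge = False
    eigs = np.linalg.eigvalsh(cov)
    if eigs.min() <= 1e-10 * max(np.trace(cov), 1.0):
        cov = cov + (1e-8 * np.trace(cov) / d) * np.eye(d)
        ridge = True
        log.warning("near-singular covariance for %s; ridge guard applied", label)
    return PopulationModel(label, mean, cov, ridge)


def similarity_score(x: np.ndarray, model: PopulationModel) -> np.ndarray | float:
    """Log multivariate-normal density of PC coordinates under the population fit."""
    x = np.asarray(x, dtype=float)
    out = stats.multivariate_normal.logpdf(x, mean=model.mean, cov=model.cov)
    return out


def qc_filter(
    pcs: pd.DataFrame,
    labels: pd.Series,
    models: dict[str, PopulationModel] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[list[str], pd.DataFrame]:
    """Drop samples whose similarity to their assigned population is ≤ cutoff.

    ``pcs`` is indexed by sample id (columns = PCs), ``labels`` maps sample id
    to its assigned population.  Models default to single-pass fits on the
    pre-filter samples of each population.  Returns the retained ids and a
    per-population report with removal counts.
    """
    labels = labels.loc[pcs.index]
    if models is None:
        models = {
            k: fit_population_model(pcs.loc[labels == k].to_numpy(), k)
            for k in labels.unique()
        }
    retained: list[str] = []
    rows = []
    for k, grp in pcs.groupby(labels):
        s = np.atleast_1d(similarity_score(grp.to_numpy(), models[k]))
        keep = s > cutoff
        retained.extend(grp.index[keep])
        rows.append({"population": k, "n": len(grp), "removed": int((~keep).sum())})
        if (~keep).any():
            log.info("ancestry QC removed %d / %d from %s", int((~keep).sum()), len(grp), k)
    report = pd.DataFrame(rows)
    retained = [s for s in pcs.index if s in set(retained)]  # preserve input order
    return retained, report
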