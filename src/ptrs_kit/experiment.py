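"""End-to-end experiment driver: simulate → predict → PVE → build → score → evaluate.

Mirrors a discovery/target design: score weights (GWAS-based PRS,
elastic-net and clumping/thresholding PTRS) are estimated on a discovery
subset of the first population; the held-out remainder of that population is
the reference target set, and every other population is an additional target
set.  Each score family is evaluated by repeated-split partial R̃², the
portability of each family in each target set is taken against the reference
set, and PRS+PTRS combinations are calibrated per target set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__, evaluate, prs, ptrs, varcomp
from .io_formats import write_scores
from .simulate import Cohort, SimConfig, simulate_cohort
from .transcriptome import inverse_normalize, predict_expression, standardize

log = logging.getLogger(__name__)


class SimulateSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_per_population: int = 1000
    n_variants: int = 400
    n_genes: int = 120
    cis_variants_per_gene: int = 3
    fst_like_divergence: float = 0.15
    mediated_h2: float = 0.25
    direct_h2: float = 0.2
    direct_effect_correlation: float = 0.0
    n_causal_variants: int = 50
    covariate_effect_sd: float = 0.3
    ld_rho: float = 0.0
    n_genotype_pcs: int = 5


class RunConfig(BaseModel):
    """Schema-validated experiment configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    simulate: SimulateSection = SimulateSection()
    trait: str = "trait"
    seed: int = 0
    discovery_fraction: float = 0.5
    alpha: float = 0.1
    penalize_covariates: bool = True
    n_repeats: int = 10
    n_en_models: int = 11
    estimate_pve: bool = True
    maf_min: float = 0.001
    hwe_p_min: float = 1e-10

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage(name: str):
    log.info("stage: %s", name)


def run_experiment(config: RunConfig, outdir: str | Path) -> dict:
    """Run the full pipeline on a simulated two-population cohort.

    Writes score TSVs, the weight paths, and a JSON report bundle with
    per-family accuracy, portability and the combined score, plus provenance
    (package version, seed, config hash).  Raises with the failing stage name
    on any error.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": config.model_dump(),
        }
    }
    stage = "simulate"
    try:
        _stage(stage)
        cfg = SimConfig(seed=config.seed, **config.simulate.model_dump())
        cohort = simulate_cohort(cfg)
        pops = list(cohort.genotypes)
        disc_pop, target_pops = pops[0], pops[1:]

        # discovery / reference-target split inside the first population
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 99]))
        ids = list(cohort.genotypes[disc_pop].sample_ids)
        perm = rng.permutation(len(ids))
        n_disc = int(round(config.discovery_fraction * len(ids)))
        disc_ids = [ids[i] for i in perm[:n_disc]]
        ref_ids = [ids[i] for i in perm[n_disc:]]

        G_disc = cohort.genotypes[disc_pop].subset_samples(disc_ids)
        pheno_disc = cohort.phenotypes[disc_pop].aligned_to(disc_ids)
        targets = {f"{disc_pop}_ref": (cohort.genotypes[disc_pop].subset_samples(ref_ids),
                                       cohort.phenotypes[disc_pop].aligned_to(ref_ids))}
        for p in target_pops:
            targets[p] = (cohort.genotypes[p], cohort.phenotypes[p])

        stage = "predict_expression"
        _stage(stage)
        expr_disc_raw = predict_expression(G_disc, cohort.weights)
        expr_disc_std = standardize(expr_disc_raw)

        if config.estimate_pve:
            stage = "pve"
            _stage(stage)
            y = pheno_disc.trait(config.trait)
            C = pheno_disc.covariates()
            K_t = varcomp.relatedness_from_features(inverse_normalize(expr_disc_raw))
            vc_t = varcomp.reml_fit(y, C, K_t)
            g_std, _ = G_disc.standardized()
            K_g = varcomp.relatedness_from_features(g_std, sample_ids=list(G_disc.sample_ids))
            vc_g = varcomp.reml_fit(y, C, K_g)
            report["pve"] = {
                "transcriptome": dataclasses.asdict(vc_t),
                "chip_h2": dataclasses.asdict(vc_g),
                "ratio": varcomp.pve_ratio(vc_t, vc_g) if vc_g.pve > 0 else None,
            }

        stage = "gwas"
        _stage(stage)
        assoc = prs.run_gwas(G_disc, pheno_disc, config.trait)
        assoc = prs.filter_variants(assoc, config.maf_min, config.hwe_p_min)
        kept = prs.ld_clump(assoc, G_disc)
        prs_path = prs.build_prs_path(assoc, kept, provenance={"discovery": disc_pop})
        prs_path.to_json(out / "prs_path.json")

        stage = "ptrs_en"
        _stage(stage)
        y = pheno_disc.trait(config.trait)
        Cmat = pheno_disc.covariates()
        C_std = (Cmat - Cmat.mean(axis=0)) / np.where(Cmat.std(axis=0) > 0, Cmat.std(axis=0), 1.0)
        X = np.column_stack([expr_disc_std.values, C_std])
        lam_max = ptrs.lambda_max(y, X, config.alpha)
        fit = ptrs.fit_elastic_net_path(
            y, expr_disc_std, C_std, alpha=config.alpha,
            grid=ptrs.lambda_grid(lam_max),
            penalize_covariates=config.penalize_covariates, seed=config.seed,
        )
        en_path = ptrs.select_nondegenerate(fit, k=config.n_en_models)
        en_path.to_json(out / "ptrs_en_path.json")

        stage = "ptrs_ct"
        _stage(stage)
        gene_assoc = ptrs.predixcan_assoc(expr_disc_std, pheno_disc, config.trait)
        kept_genes = ptrs.gene_clump(gene_assoc, expr_disc_std)
        ct_path = ptrs.build_ptrs_ct_path(gene_assoc, kept_genes)
        ct_path.to_json(out / "ptrs_ct_path.json")

        stage = "score_and_evaluate"
        _stage(stage)
        families = {"prs": prs_path, "ptrs_en": en_path, "ptrs_ct": ct_path}
        results: dict[str, dict] = {f: {} for f in families}
        combined: dict[str, dict] = {}
        scores_by_target: dict[str, dict[str, pd.DataFrame]] = {}
        for tname, (G_t, pheno_t) in targets.items():
            expr_t = standardize(predict_expression(G_t, cohort.weights))
            y_t = pheno_t.trait(config.trait)
            C_t = pheno_t.covariates()
            scores_by_target[tname] = {}
            for fam, path in families.items():
                target_obj = G_t if path.feature_space == "variant" else expr_t
                sc = prs.score(target_obj, path)
                scores_by_target[tname][fam] = sc
                write_scores(sc, out / f"scores_{fam}_{tname}.tsv")
                rep = evaluate.select_and_test(
                    sc, y_t, C_t, n_repeats=config.n_repeats, seed=config.seed,
                    support_sizes=path.support_sizes(), trait=config.trait, family=fam,
                )
                results[fam][tname] = dataclasses.asdict(rep)
            comb = evaluate.combine_scores(
                scores_by_target[tname]["prs"], scores_by_target[tname]["ptrs_en"],
                y_t, C_t, n_repeats=config.n_repeats, seed=config.seed, trait=config.trait,
            )
            combined[tname] = {
                "mean_r2": comb.mean_r2,
                "specs": [dataclasses.asdict(s) for s in comb.specs],
            }

        stage = "portability"
        _stage(stage)
        ref_name = f"{disc_pop}_ref"
        portab: dict[str, dict[str, float | None]] = {}
        for fam in families:
            ref_r2 = results[fam][ref_name]["mean_r2"]
            portab[fam] = {}
            for tname in targets:
                try:
                    portab[fam][tname] = evaluate.portability(results[fam][tname]["mean_r2"], ref_r2)
                except ZeroDivisionError:
                    portab[fam][tname] = None
        report["accuracy"] = results
        report["combined"] = combined
        report["portability"] = portab
    except Exception as exc:
        raise RuntimeError(f"experiment failed at stage {stage!r}: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True, default=float))
    tidy = []
    for fam, per_t in report["accuracy"].items():
        for tname, rep in per_t.items():
            tidy.append(
                {"family": fam, "target": tname, "mean_r2": rep["mean_r2"],
                 "portability": report["portability"][fam][tname]}
            )
    pd.DataFrame(tidy).to_csv(out / "accuracy.tsv", sep="\t", index=False)
    return report
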