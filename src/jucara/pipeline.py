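"""End-to-end pipeline: derive → fit → correlate → path → SSR → divergence.

Each stage writes its artifacts to the configured output directory and the
run log records the seed, configuration digest and package versions, so a
rerun with the same inputs and seed reproduces every numeric output.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

import jucara
from jucara import association, divergence, diversity, io, lmm, traits
from jucara.config import PipelineConfig

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def model_spec_for(trait: str, group: str, structure: str = "idv") -> lmm.ModelSpec:
    """Mixed-model form for a trait group.

    biometric — fixed replicate, random genotype, homogeneous residual;
    emergence — fixed replicate + sampling group, random genotype +
    elevation, residual variances per sampling group; growth — fixed
    replicate + evaluation time, random genotype + genotype-by-time (with the
    requested covariance structure), residual variances per time;
    physiological — fixed replicate + time, random genotype, residual per
    time.
    """
    if group == "biometric":
        return lmm.ModelSpec(
            response=trait, fixed=("replicate",), random=(lmm.RandomSpec("genotype"),)
        )
    if group == "emergence":
        return lmm.ModelSpec(
            response=trait,
            fixed=("replicate", "group"),
            random=(lmm.RandomSpec("genotype"), lmm.RandomSpec("elevation")),
            residual=lmm.ResidualSpec(by="group"),
        )
    if group == "growth":
        # CS/US among-time structures contain a compound-symmetric component
        # and are not identifiable jointly with a separate genotype main
        # effect, so those candidates absorb it into the interaction matrix.
        if structure in ("cs", "us"):
            rand: tuple[lmm.RandomSpec, ...] = (
                lmm.RandomSpec("genotype", structure=structure, by="eval_time"),
            )
        else:
            rand = (
                lmm.RandomSpec("genotype"),
                lmm.RandomSpec("genotype", structure=structure, by="eval_time"),
            )
        return lmm.ModelSpec(
            response=trait,
            fixed=("replicate", "eval_time"),
            random=rand,
            residual=lmm.ResidualSpec(by="eval_time"),
        )
    if group == "physiological":
        return lmm.ModelSpec(
            response=trait,
            fixed=("replicate", "eval_time"),
            random=(lmm.RandomSpec("genotype"),),
            residual=lmm.ResidualSpec(by="eval_time"),
        )
    raise ValueError(f"unknown trait group {group!r}")


def _reduced_spec(spec: lmm.ModelSpec) -> lmm.ModelSpec:
    """Same model without the plain genotype term (for the genotype LRT)."""
    rand = tuple(r for r in spec.random if not (r.factor == "genotype" and r.by is None))
    return lmm.ModelSpec(
        response=spec.response, fixed=spec.fixed, random=rand, residual=spec.residual
    )


def fit_trait(
    data: pd.DataFrame, trait: str, group: str, config: PipelineConfig
) -> tuple[lmm.ModelFit, dict]:
    """Fit one trait (with structure selection for growth) and summarize it."""
    if group == "growth":
        candidates = [
            model_spec_for(trait, group, structure=s) for s in config.candidate_structures
        ]
        _, best_spec, fits = lmm.select_structure(
            data, candidates, criterion=config.selection_criterion
        )
        fit = fits[best_spec.describe()]
    else:
        fit = lmm.fit_reml(data, model_spec_for(trait, group))
    reduced = lmm.fit_reml(data, _reduced_spec(fit.spec))
    test = lmm.lrt(fit, reduced)
    h2 = lmm.cullis_heritability(fit)
    _, acc = lmm.prediction_accuracy(fit)
    aic, bic, bicc = lmm.information_criteria(fit)
    resid = fit.residual_var
    resid_mean = float(np.mean(list(resid.values()))) if isinstance(resid, dict) else resid
    summary = {
        "trait": trait,
        "group": group,
        "sigma2_g": fit.sigma2_g,
        "sigma2_e": resid_mean,
        "H2": h2,
        "accuracy": acc,
        "AIC": aic,
        "BIC": bic,
        "BICc": bicc,
        "LRT": test.statistic,
        "LRT_p": test.p_value,
    }
    return fit, summary


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every applicable stage; returns the artifact dictionary.

    Stages without inputs (e.g. no phenotype file) are skipped cleanly. Any
    stage failure aborts with the stage name; artifacts written so far are
    retained on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    artifacts: dict = {"config_digest": digest}

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("jucara")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    log.info(
        "run start | seed=%s config=%s jucara=%s numpy=%s python=%s",
        config.seed,
        digest,
        jucara.__version__,
        np.__version__,
        sys.version.split()[0],
    )
    log.info(
        "settings | vif_threshold=%s mojena_k=%s mantel_B=%s criterion=%s "
        "dqi_diameter_in_cm=%s",
        config.vif_threshold,
        config.mojena_k,
        config.mantel_permutations,
        config.selection_criterion,
        config.dqi_diameter_in_cm,
    )

    def stage(name: str):
        log.info("stage %s", name)

    try:
        phen = None
        if config.phenotypes:
            stage("read_phenotypes")
            phen = io.read_phenotypes(config.phenotypes)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("read_phenotypes", exc) from exc

    try:
        if config.emergence_counts:
            stage("derive_emergence")
            counts = pd.read_csv(config.emergence_counts)
            derived = traits.derive_emergence_traits(counts)
            derived.to_csv(out / "derived_emergence.csv", index=False)
            artifacts["derived_emergence"] = derived
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("derive_emergence", exc) from exc

    blup_matrix = None
    if phen is not None and config.trait_groups:
        try:
            stage("fit_traits")
            summaries = []
            blups = {}
            for trait, group in config.trait_groups.items():
                fit, summary = fit_trait(phen, trait, group, config)
                summaries.append(summary)
                blups[trait] = fit.genotype_blups
            genpar = pd.DataFrame(summaries)
            genpar.insert(0, "config", digest)
            genpar.to_csv(out / "genetic_parameters.csv", index=False)
            artifacts["genetic_parameters"] = genpar
            blup_matrix = pd.DataFrame(blups)
            blup_matrix.to_csv(out / "blup_matrix.csv")
            artifacts["blup_matrix"] = blup_matrix
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("fit_traits", exc) from exc

        try:
            stage("correlations")
            means = phen.pivot_table(index="genotype", columns="trait", values="value")
            pheno_corr = association.phenotypic_correlation(means)
            pheno_corr.r.to_csv(out / "phenotypic_correlation.csv")
            pheno_corr.p.to_csv(out / "phenotypic_correlation_p.csv")
            artifacts["phenotypic_correlation"] = pheno_corr
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("correlations", exc) from exc

        if config.path_response in pheno_corr.labels:
            try:
                stage("path_analysis")
                resp = config.path_response
                expl = [t for t in pheno_corr.labels if t != resp]
                C = pheno_corr.r.loc[expl, expl]
                retained, vif_table = association.vif_filter(C, config.vif_threshold)
                r_y = pheno_corr.r.loc[retained, resp]
                result = association.path_analysis(
                    C.loc[retained, retained], r_y, response=resp
                )
                result.excluded = vif_table[vif_table["excluded"]]
                vif_table.to_csv(out / "vif.csv", index=False)
                edges = pd.DataFrame(
                    {
                        "trait": result.traits,
                        "direct_effect": result.direct.to_numpy(),
                        "response": resp,
                    }
                )
                edges.to_csv(out / "path_direct_effects.csv", index=False)
                artifacts["path"] = result
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("path_analysis", exc) from exc

    ssr = None
    if config.ssr:
        try:
            stage("ssr_diversity")
            ssr = io.read_ssr(config.ssr)
            summary = diversity.summarize_loci(ssr)
            summary.insert(0, "config", digest)
            summary.to_csv(out / "ssr_diversity.csv", index=False)
            artifacts["ssr_diversity"] = summary
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("ssr_diversity", exc) from exc

    try:
        matrices: dict[str, divergence.DistanceMatrix] = {}
        if blup_matrix is not None:
            stage("demp_distance")
            matrices["demp"] = divergence.demp_distance(blup_matrix)
        if ssr is not None:
            stage("ssr_distance")
            matrices["ssr"] = divergence.unweighted_ssr_distance(ssr)
        if len(matrices) == 2:
            shared = sorted(set(matrices["demp"].labels) & set(matrices["ssr"].labels))
            if len(shared) >= 3:
                matrices["demp"] = matrices["demp"].reorder(shared)
                matrices["ssr"] = matrices["ssr"].reorder(shared)
            else:
                log.warning("too few shared genotypes for fusion; skipping")
                matrices.pop("ssr")
        for name, D in list(matrices.items()):
            io.write_distance_csv(D, out / f"distance_{name}.csv")
            io.write_phylip_dist(D, out / f"distance_{name}.phy")
        if len(matrices) == 2:
            stage("fuse_and_cluster")
            n1 = divergence.normalize01(matrices["demp"])
            n2 = divergence.normalize01(matrices["ssr"])
            fused = divergence.fuse_average(n1, n2)
            io.write_distance_csv(fused, out / "distance_fused.csv")
            matrices["fused"] = fused
        for name, D in matrices.items():
            tree = divergence.upgma(D)
            io.write_newick(tree.to_newick(), out / f"upgma_{name}.nwk")
            groups, thr = divergence.mojena_cut(tree, config.mojena_k)
            gdf = groups.reset_index()
            gdf.to_csv(out / f"groups_{name}.csv", index=False)
            artifacts[f"groups_{name}"] = groups
            log.info("clusters (%s): %d groups at threshold %.4f", name, groups.nunique(), thr)
        if "demp" in matrices and "ssr" in matrices:
            stage("mantel")
            res = divergence.mantel(
                matrices["demp"],
                matrices["ssr"],
                permutations=config.mantel_permutations,
                seed=int(config.seed),
            )
            pd.DataFrame(
                [
                    {
                        "config": digest,
                        "r": res.r,
                        "permutations": res.permutations,
                        "p_value": res.p_value,
                        "seed": res.seed,
                    }
                ]
            ).to_csv(out / "mantel.csv", index=False)
            artifacts["mantel"] = res
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("divergence", exc) from exc

    log.info("run complete")
    root.removeHandler(handler)
    handler.close()
    return artifacts
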