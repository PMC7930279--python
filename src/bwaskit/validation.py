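"""Simulation studies that characterize the pipeline's operating behaviour.

Each study generates synthetic cohorts with known ground truth, runs the
corresponding analysis end to end, and reports an empirical rate:
family-wise error under the global null, planted-effect detection power,
stage specificity, and the genetic-arm recovery properties. They are the
package's own calibration evidence and are exercised by the test suite.

All studies derive per-replicate seeds deterministically from one base
seed, so a study is reproducible from a single integer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from bwaskit import bwas, clinical, prs as prsmod
from bwaskit.connectome import connectome_stack
from bwaskit.synthgen import (
    SimConfig,
    atlas_labels,
    generate_cohort,
    generate_expression,
    generate_genotypes,
)

__all__ = [
    "null_cohort_config",
    "planted_cohort_config",
    "build_stack",
    "fwer_null_calibration",
    "planted_recovery_study",
    "stage_specificity_study",
    "prs_liability_study",
    "kmeans_recovery_study",
    "prs_specificity_study",
]


def _seed(base: int, i: int) -> int:
    return int((base * 7919 + i) % (2**31 - 1))


def null_cohort_config(seed: int, n_per_group: int = 15,
                       n_timepoints: int = 150) -> SimConfig:
    """Global-null cohort on a 30-voxel grid: no coupling, no genetics."""
    return SimConfig(
        grid_shape=(5, 3, 2),
        n_patients=n_per_group,
        n_controls=n_per_group,
        n_timepoints=n_timepoints,
        blob_specs=(((0, 1, 1), 1.0, 1), ((4, 1, 1), 1.0, 2)),
        planted_edges=(),
        genetic_fc_effect=0.0,
        seed=seed,
    )


def planted_cohort_config(seed: int, delta_r: float = 0.35,
                          n_per_group: int = 40, n_timepoints: int = 200,
                          **overrides) -> SimConfig:
    """One planted blob-pair coupling on a 60-voxel grid.

    The blobs sit at opposite ends of the grid (gap >= 3 voxels) so a
    stray supra-threshold edge cannot spatially merge them.
    """
    kw = dict(
        grid_shape=(10, 3, 2),
        n_patients=n_per_group,
        n_controls=n_per_group,
        n_timepoints=n_timepoints,
        blob_specs=(((1, 1, 1), 1.0, 1), ((8, 1, 0), 1.0, 2)),
        planted_edges=((0, 1, delta_r),),
        seed=seed,
    )
    kw.update(overrides)
    return SimConfig(**kw)


def build_stack(config: SimConfig):
    """Generate a cohort and return (stack, phenotypes, truth)."""
    from bwaskit.connectome import VoxelSet

    series, pheno, truth = generate_cohort(config)
    shape = tuple(config.grid_shape)
    n = int(np.prod(shape))
    coords = np.stack(np.unravel_index(np.arange(n), shape), axis=1)
    voxels = VoxelSet(np.arange(n), coords, atlas_labels(config), shape)
    stack = connectome_stack(list(series), list(pheno["subject_id"]), voxels)
    return stack, pheno, truth


def _planted_edge_set(truth) -> set:
    return {tuple(sorted(p)) for p in truth.planted_voxel_pairs[0]["voxel_pairs"]}


def fwer_null_calibration(n_datasets: int = 300, seed: int = 1,
                          z_cdt: float = 3.1, n_perm: int = 199,
                          alpha: float = 0.05) -> dict:
    """Family-wise error of the cluster-size inference under the global null.

    Generates ``n_datasets`` independent null cohorts (30 voxels, 15+15
    subjects, 150 timepoints), runs the full edge-GLM + clustering +
    permutation inference on each, and reports the fraction of datasets
    in which any cluster reaches corrected p < alpha.
    """
    hits = 0
    for i in range(n_datasets):
        s = _seed(seed, i)
        stack, pheno, _ = build_stack(null_cohort_config(s))
        design = bwas.design_from_phenotypes(pheno)
        clusters, _ = bwas.fwer_cluster_inference(
            stack, design, z_cdt, n_perm=n_perm, seed=s)
        hits += int(any(c.corrected_p < alpha for c in clusters))
    rate = hits / n_datasets
    mc_se = float(np.sqrt(alpha * (1 - alpha) / n_datasets))
    return {"fwer": rate, "n_datasets": n_datasets, "mc_se": mc_se,
            "bound": alpha + 2 * mc_se}


def planted_recovery_study(n_runs: int = 50, seed: int = 1,
                           z_cdt: float = 4.0, n_perm: int = 199) -> dict:
    """Detection power for a planted blob-pair coupling and symptom sign.

    delta_r = 0.35, 40 patients vs 40 controls, 60 voxels. A run counts
    as detected when a cluster with corrected p < 0.05 contains planted
    edges; among detections, the covariate-adjusted partial correlation
    between cluster strength and the symptom score must recover the
    generative slope's (positive) sign.
    """
    detected = signs = 0
    for i in range(n_runs):
        s = _seed(seed, i)
        stack, pheno, truth = build_stack(planted_cohort_config(s))
        design = bwas.design_from_phenotypes(pheno)
        clusters, _ = bwas.fwer_cluster_inference(
            stack, design, z_cdt, n_perm=n_perm, seed=s)
        planted = _planted_edge_set(truth)
        hits = [c for c in clusters
                if c.corrected_p < 0.05 and set(c.edges) & planted]
        if not hits:
            continue
        detected += 1
        cl = max(hits, key=lambda c: c.size)
        pat = (pheno["group"] == 1).to_numpy()
        strength = bwas.cluster_mean_strength(stack, cl)[pat]
        covs = pheno.loc[pat, ["age", "sex", "education", "mean_fd"]]
        r = clinical.partial_correlation(
            strength, pheno.loc[pat, "panss_negative"].to_numpy(float),
            covs.to_numpy(float))
        signs += int(r > 0)
    return {
        "detection_rate": detected / n_runs,
        "sign_recovery_rate": signs / detected if detected else 0.0,
        "n_runs": n_runs,
    }


def stage_specificity_study(n_runs: int = 50, seed: int = 1,
                            z_cdt: float = 4.0, n_perm: int = 199) -> dict:
    """Stage specificity: an effect planted only in short-duration patients
    should surface in the short-stage report and not the long-stage one."""
    ok = 0
    for i in range(n_runs):
        s = _seed(seed, i)
        cfg = planted_cohort_config(s, delta_r=0.4, n_timepoints=150,
                                    stage_effect="short")
        stack, pheno, truth = build_stack(cfg)
        pat = pheno[pheno["group"] == 1]
        si, li, _med = clinical.median_split(
            pat["duration_weeks"].to_numpy(float))
        out = clinical.stage_bwas(
            stack, pheno,
            list(pat["subject_id"].iloc[si]), list(pat["subject_id"].iloc[li]),
            z_cdt, n_perm=n_perm, seed=s)
        planted = _planted_edge_set(truth)

        def hit(res):
            return any(c.corrected_p < 0.05 and set(c.edges) & planted
                       for c in res["clusters"])

        ok += int(hit(out["short"]) and not hit(out["long"]))
    return {"specificity_rate": ok / n_runs, "n_runs": n_runs}


def prs_liability_study(n_reps: int = 50, seed: int = 1,
                        n_per_group: int = 1000) -> dict:
    """Recovery of the genetic liability by the selected-SNP PRS.

    Five effect SNPs; per replicate, the full chain association ->
    anchor-cluster selection -> log-OR-weighted PRS is run and the
    Pearson correlation with the true standardized liability recorded.
    """
    corrs = []
    for i in range(n_reps):
        s = _seed(seed, i)
        cfg = SimConfig(n_patients=n_per_group, n_controls=n_per_group,
                        planted_edges=(), seed=s)
        _, pheno, _ = generate_cohort(cfg)
        dos, snp_table, gt = generate_genotypes(cfg, pheno)
        assoc, _ = prsmod.snp_association(
            dos, pheno["group"].to_numpy(int), snp_table)
        anchor_genes = [g for g, b in gt["gene_blocks"].items() if b == 0]
        ids = prsmod.select_snps(assoc, anchor_genes, 0.05)
        model = prsmod.build_prs_model(assoc, ids, 0.05, anchor_genes)
        scores = prsmod.compute_prs(dos, model, snp_table)
        corrs.append(float(np.corrcoef(scores, gt["liability"])[0, 1]))
    return {"mean_correlation": float(np.mean(corrs)),
            "min_correlation": float(np.min(corrs)), "n_reps": n_reps}


def kmeans_recovery_study(n_seeds: int = 100, seed: int = 1) -> dict:
    """Exact recovery rate of the planted anchor co-expression block."""
    ok = 0
    for i in range(n_seeds):
        s = _seed(seed, i)
        cfg = SimConfig(seed=s)
        expr = generate_expression(cfg)
        gc = prsmod.kmeans_gene_clusters(
            expr, k=cfg.n_expr_blocks, anchor_gene=cfg.anchor_gene,
            n_restarts=50, seed=s)
        ok += int(sorted(gc.anchor_members)
                  == sorted(expr.index[: cfg.anchor_cluster_size]))
    return {"recovery_rate": ok / n_seeds, "n_seeds": n_seeds}


def prs_specificity_study(n_runs: int = 50, seed: int = 1,
                          n_per_group: int = 200) -> dict:
    """Co-expression filtering specificity of the pathway PRS.

    Genetic effects are confined to anchor-cluster genes; per run the
    mean |r| between PRS and the planted cluster's strength is compared
    between the cluster-restricted and the unfiltered-panel PRS.
    """
    wins = 0
    for i in range(n_runs):
        s = _seed(seed, i)
        cfg = planted_cohort_config(s, n_per_group=n_per_group,
                                    n_timepoints=150, genetic_fc_effect=0.3)
        stack, pheno, truth = build_stack(cfg)
        dos, snp_table, gt = generate_genotypes(cfg, pheno)
        pat = (pheno["group"] == 1).to_numpy()
        planted = sorted(_planted_edge_set(truth))
        cl = bwas.FCCluster(
            planted, np.unique([p[0] for p in planted]),
            np.unique([p[1] for p in planted]), len(planted), 0, 1.0)
        strengths = pd.DataFrame(
            {"c0": bwas.cluster_mean_strength(stack, cl)[pat]})
        assoc, _ = prsmod.snp_association(
            dos, pheno["group"].to_numpy(int), snp_table)
        anchor_genes = [g for g, b in gt["gene_blocks"].items() if b == 0]
        out = prsmod.unfiltered_prs_contrast(
            dos[pat], assoc, anchor_genes, strengths, snp_table,
            n_perm=99, seed=s)
        wins += int(out["difference"] > 0)
    return {"win_rate": wins / n_runs, "n_runs": n_runs}
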