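"""File I/O, run configuration and end-to-end pipeline orchestration.

Formats: NIfTI-1 for 4D time series / mask / atlas (via nibabel), VCF
4.2 with GT genotypes (via cyvcf2), CSV with header rows for phenotype,
expression and report tables, JSON for the ground truth and the run
manifest, and an .npz container for the connectome stack.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from bwaskit import bwas, clinical, prs as prsmod
from bwaskit.connectome import (
    ConnectomeStack,
    VoxelSet,
    connectome_stack,
    exclude_high_motion,
)

log = logging.getLogger("bwaskit")

REQUIRED_PHENO_COLUMNS = (
    "subject_id", "group", "age", "sex", "education", "mean_fd",
)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Defaults mirror the reference analysis: primary CDT p = 2e-8,
    stage-specific CDT p = 3e-7, cluster alpha 0.05, 10,000 association
    permutations, FD cut 0.5 mm, band 0.01-0.1 Hz.
    """

    data_dir: str = "."
    out_dir: str = "out"
    cdt_p: float = 2e-8
    stage_cdt_p: float = 3e-7
    alpha: float = 0.05
    n_perm_cluster: int = 1000
    n_perm_assoc: int = 10_000
    fd_threshold: float = 0.5
    band_low_hz: float = 0.01
    band_high_hz: float = 0.1
    tr_seconds: float = 2.0
    kmeans_k: int = 5
    kmeans_restarts: int = 50
    prs_p_threshold: float = 0.05
    anchor_gene: str = "FOXP2"
    symptom_score: str = "panss_negative"
    cdt_sided: str = "one"
    adjust_prs: bool = False
    seeds: dict = field(default_factory=lambda: {
        "cluster": 11, "stage": 13, "assoc": 17, "kmeans": 19, "prs": 23,
    })

    def __post_init__(self) -> None:
        for name in ("cdt_p", "stage_cdt_p", "alpha", "prs_p_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.n_perm_cluster < 99 or self.n_perm_assoc < 99:
            raise ValueError("permutation counts must be >= 99")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# readers

def read_nifti_stack(paths, mask_path, atlas_path=None):
    """Load per-subject 4D NIfTI series restricted to a mask.

    Returns ``(series_list, voxels)``: each series is time x voxels over
    the in-mask voxels in row-major grid order; voxel coordinates are
    0-based grid indices. All images must agree in spatial shape and
    affine.
    """
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj) > 0
    shape, affine = mask.shape, mask_img.affine
    flat = mask.reshape(-1)
    vox_rows = np.flatnonzero(flat)
    coords = np.stack(np.unravel_index(vox_rows, shape), axis=1)
    if atlas_path is not None:
        atlas_img = nib.load(str(atlas_path))
        if atlas_img.shape != shape or not np.allclose(atlas_img.affine, affine):
            raise ValueError(f"atlas mismatches mask: {atlas_path}")
        labels = np.asarray(atlas_img.dataobj).reshape(-1)[vox_rows].astype(int)
    else:
        labels = np.zeros(len(vox_rows), dtype=int)
    voxels = VoxelSet(np.arange(len(vox_rows)), coords, labels, shape)

    series = []
    for p in paths:
        img = nib.load(str(p))
        if img.shape[:3] != shape:
            raise ValueError(f"shape mismatch in {p}: {img.shape[:3]} vs {shape}")
        if not np.allclose(img.affine, affine, atol=1e-6):
            raise ValueError(f"affine mismatch in {p}")
        data = np.asarray(img.dataobj, dtype=np.float32)
        series.append(data.reshape(-1, data.shape[3])[vox_rows].T)
    return series, voxels


def read_vcf_dosages(path, max_missing: float = 0.05):
    """ALT-allele dosages and a SNP table from a VCF with GT fields.

    Multiallelic records are skipped with a warning; SNPs with more than
    ``max_missing`` missing genotypes are excluded, remaining missing
    calls are mean-imputed (both logged).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, rows = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(f"skipping multiallelic record {var.ID}")
            continue
        gt = np.asarray(var.gt_types)  # 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        dos = np.where(gt == 3, 2.0, gt.astype(float))
        miss = gt == 2
        if miss.mean() > max_missing:
            log.warning("excluding %s: %.1f%% missing", var.ID, 100 * miss.mean())
            continue
        if miss.any():
            dos[miss] = dos[~miss].mean()
            log.info("mean-imputed %d calls for %s", miss.sum(), var.ID)
        gene = var.INFO.get("GENE", "")
        rows.append({"snp_id": var.ID, "gene": gene, "ref": var.REF,
                     "alt": var.ALT[0]})
        cols.append(dos)
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return dosages, pd.DataFrame(rows), samples


# ---------------------------------------------------------------------------
# stack container

def write_stack(stack: ConnectomeStack, prefix) -> dict:
    """Persist a ConnectomeStack as .npz plus an edge-index CSV."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    npz = str(prefix) + ".npz"
    np.savez_compressed(
        npz,
        data=stack.data,
        subject_ids=np.array(stack.subject_ids, dtype=object),
        coords=stack.voxels.coords,
        labels=stack.voxels.labels,
        mask_shape=np.array(stack.voxels.mask_shape),
        provenance=json.dumps(stack.provenance, default=str),
    )
    iu, ju = stack.edges
    edge_csv = str(prefix) + "_edges.csv"
    pd.DataFrame({"voxel_i": iu, "voxel_j": ju}).to_csv(edge_csv, index=False)
    return {"stack": npz, "edges": edge_csv}


def read_stack(prefix) -> ConnectomeStack:
    with np.load(str(prefix) + ".npz", allow_pickle=True) as z:
        voxels = VoxelSet(
            np.arange(len(z["coords"])), z["coords"], z["labels"],
            tuple(int(v) for v in z["mask_shape"]),
        )
        return ConnectomeStack(
            list(z["subject_ids"]), voxels, z["data"],
            json.loads(str(z["provenance"])),
        )


def write_ma_map(ma: np.ndarray, voxels: VoxelSet, path,
                 affine=None) -> None:
    """Write the per-voxel measure-of-association map as integer NIfTI."""
    vol = np.zeros(voxels.mask_shape, dtype=np.int32)
    vol[tuple(voxels.coords.T)] = ma
    if affine is None:
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def cluster_report(clusters, voxels) -> pd.DataFrame:
    """One row per FC cluster: size, sign counts, labels, corrected p."""
    rows = []
    for ci, cl in enumerate(clusters):
        l1, l2 = bwas.label_cluster(cl, voxels)
        rows.append({
            "cluster": ci, "size": cl.size,
            "n_increased": cl.n_increased, "n_decreased": cl.n_decreased,
            "region1": l1, "region2": l2,
            "region1_tie": cl.label1_tie, "region2_tie": cl.label2_tie,
            "mean_z": cl.mean_z, "corrected_p": cl.corrected_p,
            "significant": cl.extra.get("significant"),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline

def _validate_inputs(cfg: RunConfig) -> dict:
    d = Path(cfg.data_dir)
    paths = {
        "phenotypes": d / "phenotypes.csv",
        "mask": d / "mask.nii.gz",
        "atlas": d / "atlas.nii.gz",
        "vcf": d / "genotypes.vcf",
        "expression": d / "expression.csv",
    }
    for name, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"missing input {name}: {p}")
    pheno = pd.read_csv(paths["phenotypes"])
    missing = [c for c in REQUIRED_PHENO_COLUMNS if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    if cfg.symptom_score not in pheno.columns:
        raise ValueError(f"phenotype table lacks symptom column "
                         f"{cfg.symptom_score!r}")
    paths["subjects"] = {
        sid: d / f"{sid}_bold.nii.gz" for sid in pheno["subject_id"]
    }
    gone = [s for s, p in paths["subjects"].items() if not p.exists()]
    if gone:
        raise FileNotFoundError(f"missing 4D series for subjects {gone[:5]}")
    return {"paths": paths, "phenotypes": pheno}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis on an on-disk dataset.

    Stages: motion exclusion -> connectome -> edge-wise cluster FWER
    inference -> symptom association -> duration median split with
    stage-specific analyses -> pathway PRS arm. Writes all report
    tables, an MA-map NIfTI and a machine-readable run manifest; rerun
    with identical config reproduces all outputs.
    """
    inputs = _validate_inputs(cfg)
    paths, pheno = inputs["paths"], inputs["phenotypes"]
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    keep = exclude_high_motion(pheno, cfg.fd_threshold)
    pheno = pheno[pheno["subject_id"].isin(keep)].reset_index(drop=True)
    log.info("retained %d subjects after FD cut", len(pheno))

    series, voxels = read_nifti_stack(
        [paths["subjects"][s] for s in pheno["subject_id"]],
        paths["mask"], paths["atlas"],
    )
    stack = connectome_stack(
        series, list(pheno["subject_id"]), voxels,
        low_hz=cfg.band_low_hz, high_hz=cfg.band_high_hz, tr=cfg.tr_seconds,
    )
    written.update(write_stack(stack, out / "stack"))

    design = bwas.design_from_phenotypes(pheno)
    z_cdt = bwas.cdt_from_p(cfg.cdt_p, cfg.cdt_sided)
    clusters, info = bwas.fwer_cluster_inference(
        stack, design, z_cdt, n_perm=cfg.n_perm_cluster,
        seed=cfg.seeds["cluster"], alpha=cfg.alpha,
    )
    report = cluster_report(clusters, voxels)
    report.to_csv(out / "clusters.csv", index=False)
    written["clusters"] = str(out / "clusters.csv")

    sig = [cl for cl in clusters if cl.extra.get("significant")]
    sig_edges = [e for cl in sig for e in cl.edges]
    stat = info["stat"]
    iu, ju = stack.edges
    supra = np.abs(stat.z) >= z_cdt
    pd.DataFrame({
        "voxel_i": iu[supra], "voxel_j": ju[supra], "z": stat.z[supra],
    }).to_csv(out / "significant_edges.csv", index=False)
    written["significant_edges"] = str(out / "significant_edges.csv")
    ma = bwas.measure_of_association(sig_edges, len(voxels))
    write_ma_map(ma, voxels, out / "ma_map.nii.gz")
    written["ma_map"] = str(out / "ma_map.nii.gz")

    # symptom associations on significant clusters, patients only
    patients = pheno["group"] == 1
    assoc_path = out / "symptom_associations.csv"
    if sig:
        strengths = pd.DataFrame({
            f"c{ci}": bwas.cluster_mean_strength(stack, cl)[patients.to_numpy()]
            for ci, cl in enumerate(sig)
        })
        covs = pheno.loc[patients, ["age", "sex", "education", "mean_fd"]]
        clinical.association_table(
            strengths,
            pheno.loc[patients, cfg.symptom_score].to_numpy(float),
            covs.to_numpy(float),
            n_perm=cfg.n_perm_assoc, seed=cfg.seeds["assoc"],
        ).to_csv(assoc_path, index=False)
    else:
        pd.DataFrame(columns=["cluster", "r", "p", "q"]).to_csv(
            assoc_path, index=False)
    written["symptom_associations"] = str(assoc_path)

    # stage split: each duration subgroup vs all controls
    pat = pheno[patients]
    short_i, long_i, median = clinical.median_split(
        pat["duration_weeks"].to_numpy(float))
    short_ids = list(pat["subject_id"].iloc[short_i])
    long_ids = list(pat["subject_id"].iloc[long_i])
    stage_z = bwas.cdt_from_p(cfg.stage_cdt_p, cfg.cdt_sided)
    stages = clinical.stage_bwas(
        stack, pheno, short_ids, long_ids, stage_z,
        n_perm=cfg.n_perm_cluster, seed=cfg.seeds["stage"], alpha=cfg.alpha,
    )
    for name in ("short", "long"):
        p = out / f"clusters_{name}.csv"
        cluster_report(stages[name]["clusters"], voxels).to_csv(p, index=False)
        written[f"clusters_{name}"] = str(p)

    # pathway PRS arm
    dosages, snp_table, samples = read_vcf_dosages(paths["vcf"])
    order = {s: i for i, s in enumerate(samples)}
    rows = [order[s] for s in pheno["subject_id"]]
    dosages = dosages[rows]
    assoc, mono = prsmod.snp_association(
        dosages.astype(int), pheno["group"].to_numpy(int), snp_table)
    pd.DataFrame([{
        "snp_id": a.snp_id, "gene": a.gene, "or": a.odds_ratio,
        "log_or": a.log_or, "p": a.p_value, "corrected": a.corrected,
    } for a in assoc]).to_csv(out / "snp_associations.csv", index=False)
    written["snp_associations"] = str(out / "snp_associations.csv")

    expr = pd.read_csv(paths["expression"], index_col=0)
    gc = prsmod.kmeans_gene_clusters(
        expr, k=cfg.kmeans_k, anchor_gene=cfg.anchor_gene,
        n_restarts=cfg.kmeans_restarts, seed=cfg.seeds["kmeans"],
    )
    with open(out / "gene_clusters.json", "w") as fh:
        json.dump({"assignments": gc.assignments,
                   "anchor_members": gc.anchor_members}, fh, indent=1)
    written["gene_clusters"] = str(out / "gene_clusters.json")

    snp_ids = prsmod.select_snps(assoc, gc.anchor_members, cfg.prs_p_threshold)
    prs_path = out / "prs_scores.csv"
    prs_fc_path = out / "prs_fc_correlations.csv"
    if snp_ids and sig:
        model = prsmod.build_prs_model(assoc, snp_ids, cfg.prs_p_threshold,
                                       gc.anchor_members)
        scores = prsmod.compute_prs(dosages, model, snp_table)
        pd.DataFrame({"subject_id": pheno["subject_id"], "prs": scores}
                     ).to_csv(prs_path, index=False)
        pat_scores = scores[patients.to_numpy()]
        strengths = pd.DataFrame({
            f"c{ci}": bwas.cluster_mean_strength(stack, cl)[patients.to_numpy()]
            for ci, cl in enumerate(sig)
        })
        covs = (pheno.loc[patients, ["age", "sex", "education", "mean_fd"]]
                .to_numpy(float) if cfg.adjust_prs else None)
        prsmod.prs_fc_correlation(
            pat_scores, strengths, covs,
            n_perm=cfg.n_perm_assoc, seed=cfg.seeds["prs"],
        ).to_csv(prs_fc_path, index=False)
    else:
        log.warning("PRS arm skipped: %s",
                    "no SNPs selected" if not snp_ids else "no significant clusters")
        pd.DataFrame(columns=["subject_id", "prs"]).to_csv(prs_path, index=False)
        pd.DataFrame(columns=["cluster", "r", "p"]).to_csv(prs_fc_path, index=False)
    written["prs_scores"] = str(prs_path)
    written["prs_fc_correlations"] = str(prs_fc_path)

    import bwaskit

    manifest = {
        "package_version": bwaskit.__version__,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "z_cdt": z_cdt, "stage_z_cdt": stage_z,
        "duration_median_weeks": median,
        "n_subjects": int(len(pheno)),
        "n_significant_clusters": int(len(sig)),
        "monomorphic_snps": mono,
        "outputs": written,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    written["manifest"] = str(out / "manifest.json")
    return manifest
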