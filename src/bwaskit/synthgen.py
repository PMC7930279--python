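"""Synthetic cohorts with planted dysconnectivity and genetic effects.

Generates, from one seeded configuration: voxel time series for a
two-group cohort with planted between-blob connectivity differences,
a phenotype table (demographics, motion, illness duration, symptom
scores), biallelic genotypes with planted case/control odds ratios and a
genotype-to-connectivity liability pathway, and block-structured
gene-by-region expression profiles. Every draw is recorded in a
GroundTruth object so downstream inference can be scored against the
planted truth.

The generative model for connectivity: each spatial blob has one shared
regional factor; for a planted blob pair the two factors are drawn
bivariate normal with per-subject correlation

    rho_i = baseline + delta_r * 1[patient]
            + genetic_fc_effect * liability_i + noise,

so the patient-minus-control difference in blob-to-blob correlation is
delta_r on average. Voxel series mix the regional factor with white
noise; the voxel-level correlation is attenuated by the voxel-noise
share (recorded in GroundTruth.attenuation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_genotypes",
    "generate_expression",
    "generate_dataset",
    "write_fixture",
]

# stable per-stream offsets so generate_genotypes(config, pheno) reproduces
# the draw that generate_cohort made internally for the liability pathway
_STREAMS = {"phenotypes": 1, "genotypes": 2, "coupling": 3, "timeseries": 4,
            "expression": 5, "symptoms": 6}


def _rng(config: "SimConfig", stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(int(config.seed), _STREAMS[stream]))
    )


@dataclass
class SimConfig:
    """Configuration for one synthetic cohort.

    Defaults mirror the structure of a two-site first-episode
    schizophrenia study: 138 drug-naive patients vs 112 controls,
    illness duration uniform on 1-100 weeks, an 88-SNP panel over a
    20-gene language/development panel with a co-expression anchor gene.
    """

    grid_shape: tuple = (10, 4, 3)
    n_patients: int = 138
    n_controls: int = 112
    n_timepoints: int = 240
    tr_seconds: float = 2.0
    # (center, radius, atlas label) per blob; centers are 0-based grid
    # coords. Blobs are kept >= 4 voxels apart: a single stray
    # supra-threshold edge contributes two (possibly mutually adjacent)
    # endpoint voxels, which can spatially bridge two clusters separated
    # by up to 3 voxels and reclassify every planted edge as
    # within-cluster.
    blob_specs: tuple = (((1, 1, 1), 1.0, 1), ((8, 2, 1), 1.0, 2))
    # (blob index a, blob index b, delta_r) per planted coupling
    planted_edges: tuple = ((0, 1, 0.35),)
    # restrict the planted group effect to one illness-duration stratum
    # (None = all patients; "short"/"long" = at/below vs above the median)
    stage_effect: str | None = None
    baseline_coupling: float = 0.10
    subject_coupling_sd: float = 0.10
    voxel_noise_share: float = 0.30
    symptom_effect: float = 20.0
    symptom_noise_sd: float = 3.0
    duration_range_weeks: tuple = (1.0, 100.0)
    n_snps: int = 88
    n_genes: int = 20
    maf_range: tuple = (0.05, 0.40)
    disease_logor: tuple = (0.7, 0.7, 0.7, 0.7, 0.7)
    genetic_fc_effect: float = 0.0
    expr_regions: int = 60
    n_expr_blocks: int = 4
    expr_noise_sd: float = 0.30
    anchor_gene: str = "FOXP2"
    anchor_cluster_size: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 4 for d in self.grid_shape) and int(np.prod(self.grid_shape)) < 16:
            raise ValueError("grid too small; need at least ~16 voxels")
        if self.n_patients <= 0 or self.n_controls <= 0:
            raise ValueError("subject counts must be positive")
        if self.n_timepoints < 32:
            raise ValueError("n_timepoints must be >= 32")
        lo, hi = self.maf_range
        if not (0 < lo < hi < 0.5):
            raise ValueError("maf_range must satisfy 0 < low < high < 0.5")
        for a, b, dr in self.planted_edges:
            if not (-1 < dr < 1):
                raise ValueError("delta_r must lie in (-1, 1)")
            if a == b:
                raise ValueError("planted edge must join two distinct blobs")
        if self.anchor_cluster_size > self.n_genes:
            raise ValueError("anchor_cluster_size cannot exceed n_genes")
        if not (0 < self.voxel_noise_share < 1):
            raise ValueError("voxel_noise_share must be in (0, 1)")


@dataclass
class GroundTruth:
    """Planted truth for one synthetic cohort."""

    blob_voxels: list = field(default_factory=list)      # voxel ids per blob
    planted_voxel_pairs: list = field(default_factory=list)  # per planted edge
    coupling: np.ndarray | None = None   # subjects x planted edges, true rho_i
    attenuation: float = 1.0             # voxel-level r = attenuation * rho
    symptom_slope: float = 0.0
    effect_snps: list = field(default_factory=list)
    effect_logor: list = field(default_factory=list)
    liability: np.ndarray | None = None  # standardized genetic liability
    gene_blocks: dict = field(default_factory=dict)      # gene -> block id

    def to_jsonable(self) -> dict:
        d = asdict(self)
        for k in ("coupling", "liability"):
            if d[k] is not None:
                d[k] = np.asarray(d[k]).tolist()
        return d


# ---------------------------------------------------------------------------
# blobs and voxel geometry

def blob_voxel_ids(config: SimConfig) -> list[np.ndarray]:
    """Voxel ids (row-major over the grid) for each spherical blob."""
    shape = tuple(config.grid_shape)
    coords = np.stack(np.unravel_index(np.arange(np.prod(shape)), shape), axis=1)
    out = []
    for center, radius, _label in config.blob_specs:
        d2 = np.sum((coords - np.asarray(center)) ** 2, axis=1)
        ids = np.flatnonzero(d2 <= radius**2 + 1e-9)
        if ids.size == 0:
            raise ValueError(f"blob at {center} contains no voxels")
        out.append(ids)
    all_ids = np.concatenate(out)
    if len(np.unique(all_ids)) != len(all_ids):
        raise ValueError("blobs overlap; blob voxel sets must be disjoint")
    return out


def atlas_labels(config: SimConfig) -> np.ndarray:
    """Per-voxel atlas label; 0 outside every blob."""
    labels = np.zeros(int(np.prod(config.grid_shape)), dtype=np.intp)
    for ids, (_c, _r, label) in zip(blob_voxel_ids(config), config.blob_specs):
        labels[ids] = label
    return labels


# ---------------------------------------------------------------------------
# phenotypes

def _phenotypes(config: SimConfig) -> pd.DataFrame:
    rng = _rng(config, "phenotypes")
    n = config.n_patients + config.n_controls
    group = np.r_[np.ones(config.n_patients, int), np.zeros(config.n_controls, int)]
    # mild group imbalance in demographics, as observed in case/control cohorts
    age = np.where(group == 1, rng.normal(24.0, 8.0, n), rng.normal(24.5, 6.3, n))
    sex = (rng.random(n) < np.where(group == 1, 0.57, 0.45)).astype(int)
    edu = np.where(group == 1, rng.normal(11.6, 2.8, n), rng.normal(12.8, 3.0, n))
    fd = np.clip(np.abs(rng.normal(0.18, 0.09, n)), 0.02, 0.8)
    lo, hi = config.duration_range_weeks
    duration = np.where(group == 1, rng.uniform(lo, hi, n), np.nan)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "group": group,
            "age": np.round(age, 2),
            "sex": sex,
            "education": np.round(np.clip(edu, 6, 22), 2),
            "mean_fd": np.round(fd, 4),
            "duration_weeks": np.round(duration, 2),
        }
    )


# ---------------------------------------------------------------------------
# genotypes

def _solve_group_freqs(p_overall: float, log_or: float, w_case: float):
    """Case/control allele frequencies with a given allelic log-OR whose
    case-weighted mixture equals the overall frequency."""
    if log_or == 0.0:
        return p_overall, p_overall

    def f(p0):
        return w_case * expit(logit(p0) + log_or) + (1 - w_case) * p0 - p_overall

    p0 = brentq(f, 1e-6, 1 - 1e-6)
    return expit(logit(p0) + log_or), p0


def _gene_panel(config: SimConfig) -> tuple[list[str], list[str], dict]:
    """Gene names, SNP->gene map, and true expression block per gene."""
    genes = [config.anchor_gene] + [f"GENE{i:02d}" for i in range(1, config.n_genes)]
    n_blocks = max(2, min(config.n_expr_blocks, config.n_genes // 2))
    blocks = {}
    for i, g in enumerate(genes):
        if i < config.anchor_cluster_size:
            blocks[g] = 0
        else:
            blocks[g] = 1 + (i - config.anchor_cluster_size) % (n_blocks - 1)
    # SNPs spread contiguously across genes, anchor-block genes first, so
    # that effect SNPs (the first ones) land in anchor-cluster genes
    snp_gene = [genes[i % config.n_genes] for i in range(config.n_snps)]
    snp_gene.sort(key=lambda g: (blocks[g], genes.index(g)))
    return genes, snp_gene, blocks


def generate_genotypes(config: SimConfig, phenotypes: pd.DataFrame):
    """Biallelic dosages under Hardy-Weinberg with planted case/control ORs.

    Returns ``(dosages, snp_table, truth_update)`` where ``dosages`` is
    subjects x SNPs in {0,1,2}, ``snp_table`` maps each SNP to its gene
    and drawn minor-allele frequency, and ``truth_update`` carries the
    effect-SNP ids, their true log-ORs and the standardized genetic
    liability. Deterministic given ``config.seed`` alone, so the same
    matrix is reproduced wherever it is derived.
    """
    if "group" not in phenotypes.columns:
        raise KeyError("phenotypes must include a case/control 'group' column")
    n_effect = len(config.disease_logor)
    if config.n_snps < n_effect:
        raise ValueError("n_snps is smaller than the number of effect SNPs")
    rng = _rng(config, "genotypes")
    group = phenotypes["group"].to_numpy(int)
    n = len(group)
    w_case = group.mean()
    mafs = rng.uniform(*config.maf_range, size=config.n_snps)
    _genes, snp_gene, blocks = _gene_panel(config)

    dos = np.empty((n, config.n_snps), dtype=np.int16)
    true_logor = np.zeros(config.n_snps)
    true_logor[:n_effect] = config.disease_logor
    for s in range(config.n_snps):
        p1, p0 = _solve_group_freqs(mafs[s], true_logor[s], w_case)
        p = np.where(group == 1, p1, p0)
        dos[:, s] = rng.binomial(2, p)  # HWE within group

    snp_ids = [f"rs{100000 + s}" for s in range(config.n_snps)]
    snp_table = pd.DataFrame(
        {"snp_id": snp_ids, "gene": snp_gene, "maf": np.round(mafs, 4),
         "true_logor": true_logor}
    )
    raw = dos @ true_logor
    sd = raw.std()
    liability = (raw - raw.mean()) / sd if sd > 0 else np.zeros(n)
    truth = {
        "effect_snps": snp_ids[:n_effect],
        "effect_logor": list(config.disease_logor),
        "liability": liability,
        "gene_blocks": blocks,
    }
    return dos, snp_table, truth


# ---------------------------------------------------------------------------
# cohort time series

def generate_cohort(config: SimConfig):
    """Voxel time series, phenotypes, and ground truth for one cohort.

    Returns ``(series, phenotypes, truth)``: ``series`` is a
    (subjects, timepoints, voxels) float32 array over the full grid in
    row-major voxel order; ``truth`` is a :class:`GroundTruth`.
    """
    blobs = blob_voxel_ids(config)
    for a, b, _dr in config.planted_edges:
        if not (0 <= a < len(blobs) and 0 <= b < len(blobs)):
            raise ValueError("planted edge references an unknown blob")
    # each blob may take part in at most one planted coupling
    used = [i for a, b, _ in config.planted_edges for i in (a, b)]
    if len(set(used)) != len(used):
        raise ValueError("a blob may appear in at most one planted edge")

    pheno = _phenotypes(config)
    n = len(pheno)
    patient = pheno["group"].to_numpy(int) == 1

    liability = np.zeros(n)
    truth = GroundTruth(symptom_slope=config.symptom_effect,
                        attenuation=1.0 - config.voxel_noise_share)
    if config.genetic_fc_effect != 0.0:
        _dos, _snps, gt_up = generate_genotypes(config, pheno)
        liability = gt_up["liability"]
        truth.effect_snps = gt_up["effect_snps"]
        truth.effect_logor = gt_up["effect_logor"]
        truth.liability = liability
        truth.gene_blocks = gt_up["gene_blocks"]

    affected = patient.copy()
    if config.stage_effect is not None:
        if config.stage_effect not in ("short", "long"):
            raise ValueError("stage_effect must be None, 'short' or 'long'")
        dur = pheno["duration_weeks"].to_numpy(float)
        med = np.median(dur[patient])
        stratum = dur <= med if config.stage_effect == "short" else dur > med
        affected &= stratum

    rng_c = _rng(config, "coupling")
    n_pairs = len(config.planted_edges)
    rho = np.zeros((n, n_pairs))
    for k, (_a, _b, dr) in enumerate(config.planted_edges):
        rho[:, k] = (
            config.baseline_coupling
            + dr * affected
            + config.genetic_fc_effect * liability
            + rng_c.normal(0.0, config.subject_coupling_sd, n)
        )
    rho = np.clip(rho, -0.90, 0.90)

    t = config.n_timepoints
    n_vox = int(np.prod(config.grid_shape))
    paired = {a: (k, 0) for k, (a, _b, _d) in enumerate(config.planted_edges)}
    paired.update({b: (k, 1) for k, (_a, b, _d) in enumerate(config.planted_edges)})
    share = config.voxel_noise_share
    w_sig, w_noise = np.sqrt(1 - share), np.sqrt(share)

    rng_t = _rng(config, "timeseries")
    series = np.empty((n, t, n_vox), dtype=np.float32)
    for i in range(n):
        x = rng_t.standard_normal((t, n_vox))  # background + voxel noise
        factors = rng_t.standard_normal((t, len(blobs)))
        for k, (a, b, _d) in enumerate(config.planted_edges):
            r = rho[i, k]
            factors[:, b] = r * factors[:, a] + np.sqrt(1 - r**2) * factors[:, b]
        for bi, ids in enumerate(blobs):
            x[:, ids] = w_sig * factors[:, [bi]] + w_noise * x[:, ids]
        series[i] = x

    rng_s = _rng(config, "symptoms")
    mean_rho = rho.mean(axis=1) if n_pairs else np.zeros(n)
    panss_neg = np.where(
        patient,
        15.0 + config.symptom_effect * (mean_rho - config.baseline_coupling)
        + rng_s.normal(0, config.symptom_noise_sd, n),
        np.nan,
    )
    panss_pos = np.where(patient, rng_s.normal(20.5, 5.7, n), np.nan)
    pheno = pheno.assign(
        panss_negative=np.round(panss_neg, 2), panss_positive=np.round(panss_pos, 2)
    )

    truth.blob_voxels = [ids.tolist() for ids in blobs]
    truth.planted_voxel_pairs = [
        {"blobs": (a, b), "delta_r": dr,
         "voxel_pairs": [(int(i), int(j)) for i in blobs[a] for j in blobs[b]]}
        for (a, b, dr) in config.planted_edges
    ]
    truth.coupling = rho
    return series, pheno, truth


# ---------------------------------------------------------------------------
# expression

def generate_expression(config: SimConfig) -> pd.DataFrame:
    """Gene-by-region expression with planted co-expression blocks.

    Genes in the same block share a regional mean profile plus i.i.d.
    noise, so within-block correlation exceeds between-block correlation.
    The anchor gene is always a member of block 0, whose size is
    ``anchor_cluster_size``. Emulates whole-brain expression profiles of
    the kind used for gene co-expression clustering.
    """
    if config.expr_regions < 3:
        raise ValueError("expr_regions must be >= 3")
    if config.anchor_cluster_size < 2:
        raise ValueError("anchor_cluster_size must be >= 2")
    rng = _rng(config, "expression")
    genes, _snp_gene, blocks = _gene_panel(config)
    n_blocks = max(b for b in blocks.values()) + 1
    profiles = rng.normal(0.0, 1.0, size=(n_blocks, config.expr_regions))
    data = np.empty((config.n_genes, config.expr_regions))
    for i, g in enumerate(genes):
        data[i] = profiles[blocks[g]] + rng.normal(
            0.0, config.expr_noise_sd, config.expr_regions
        )
    return pd.DataFrame(
        data, index=pd.Index(genes, name="gene"),
        columns=[f"region{r:03d}" for r in range(config.expr_regions)],
    )


def generate_dataset(config: SimConfig):
    """Full bundle: (series, phenotypes, dosages, snp_table, expression, truth)."""
    series, pheno, truth = generate_cohort(config)
    dos, snp_table, gt_up = generate_genotypes(config, pheno)
    truth.effect_snps = gt_up["effect_snps"]
    truth.effect_logor = gt_up["effect_logor"]
    truth.liability = gt_up["liability"]
    truth.gene_blocks = gt_up["gene_blocks"]
    expr = generate_expression(config)
    return series, pheno, dos, snp_table, expr, truth


# ---------------------------------------------------------------------------
# fixture writing

def _write_vcf(path: Path, dosages: np.ndarray, snp_table: pd.DataFrame,
               subject_ids: list[str]) -> None:
    """Minimal VCF 4.2 with GT genotypes (unphased, ALT-dosage encoded)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(subject_ids) + "\n")
        for s, row in enumerate(snp_table.itertuples(index=False)):
            gts = "\t".join(gt_map[int(d)] for d in dosages[:, s])
            fh.write(f"1\t{1000 + 10 * s}\t{row.snp_id}\tA\tG\t.\tPASS\t"
                     f"GENE={row.gene}\tGT\t{gts}\n")


def write_fixture(cohort, genotypes, expression: pd.DataFrame, out_dir,
                  config: SimConfig) -> dict:
    """Write a full on-disk fixture; returns the path of every artifact.

    Layout: one 4D NIfTI per subject (x, y, z, t; float32), mask and
    atlas NIfTI, phenotype CSV, VCF 4.2 with GT fields, expression CSV,
    and a ground-truth JSON. Round-trips losslessly through the
    :mod:`bwaskit.io` readers (dosages exactly, series to float32).
    """
    import nibabel as nib

    series, pheno, truth = cohort
    dosages, snp_table, _gt = genotypes
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    shape = tuple(config.grid_shape)
    affine = np.diag([3.0, 3.0, 3.0, 1.0])  # 3 mm isotropic grid

    paths = {"subjects": []}
    for i, sid in enumerate(pheno["subject_id"]):
        # series is (t, voxels row-major); move time last for NIfTI
        vol = np.moveaxis(
            series[i].reshape((config.n_timepoints,) + shape), 0, -1
        ).astype(np.float32)
        p = out / f"{sid}_bold.nii.gz"
        nib.save(nib.Nifti1Image(vol, affine), p)
        paths["subjects"].append(str(p))

    mask = np.ones(shape, dtype=np.int16)
    atlas = atlas_labels(config).reshape(shape).astype(np.int16)
    paths["mask"] = str(out / "mask.nii.gz")
    paths["atlas"] = str(out / "atlas.nii.gz")
    nib.save(nib.Nifti1Image(mask, affine), paths["mask"])
    nib.save(nib.Nifti1Image(atlas, affine), paths["atlas"])

    paths["phenotypes"] = str(out / "phenotypes.csv")
    pheno.to_csv(paths["phenotypes"], index=False)
    paths["vcf"] = str(out / "genotypes.vcf")
    _write_vcf(Path(paths["vcf"]), dosages, snp_table, list(pheno["subject_id"]))
    paths["snp_table"] = str(out / "snp_table.csv")
    snp_table.to_csv(paths["snp_table"], index=False)
    paths["expression"] = str(out / "expression.csv")
    expression.to_csv(paths["expression"])
    paths["ground_truth"] = str(out / "ground_truth.json")
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=1)
    return paths
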