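"""Edge-wise brain-wide association with FC-cluster FWER inference.

The group analysis proceeds in four steps:

1. an edge-wise general linear model compares Fisher-z connectivity
   between groups with nuisance covariates, yielding a z-statistic per
   voxel-voxel edge;
2. a cluster-defining threshold (CDT) admits edges with |z| >= z_cdt;
3. supra-threshold edges whose endpoints fall in the same pair of two
   distinct spatially contiguous voxel clusters are grouped into one
   functional-connectivity (FC) cluster, whose size is its edge count;
4. cluster-size family-wise error is controlled by a Freedman-Lane
   max-statistic permutation null: covariate-adjusted residuals are
   permuted, the model refit and re-clustered, and each observed
   cluster's corrected p is the exceedance rate of the permutation
   distribution of the maximum cluster size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.special import ndtri_exp

from bwaskit.connectome import ConnectomeStack, VoxelSet

__all__ = [
    "Design",
    "EdgeStatResult",
    "FCCluster",
    "design_from_phenotypes",
    "edge_glm",
    "cdt_from_p",
    "form_fc_clusters",
    "fwer_cluster_inference",
    "measure_of_association",
    "label_cluster",
    "cluster_mean_strength",
    "replicate_clusters",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Design:
    """Group-comparison design: intercept + group indicator + covariates."""

    group: np.ndarray            # 1 = patient, 0 = control
    covariates: np.ndarray       # n x k (may have zero columns)
    subject_ids: list

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.ndim == 1:
            self.covariates = self.covariates[:, None]
        if self.covariates.size == 0:
            self.covariates = np.empty((len(self.group), 0))
        n = len(self.group)
        if self.covariates.shape[0] != n or len(self.subject_ids) != n:
            raise ValueError("design rows misaligned")
        if len(np.unique(self.group)) < 2:
            raise ValueError("group indicator must contain both classes")
        x = self.matrix
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError("design matrix is rank deficient (collinear columns)")
        if n <= x.shape[1] + 2:
            raise ValueError("too few subjects for the number of regressors")

    @property
    def matrix(self) -> np.ndarray:
        n = len(self.group)
        return np.column_stack([np.ones(n), self.group, self.covariates])

    @property
    def reduced_matrix(self) -> np.ndarray:
        """Nuisance-only design (intercept + covariates, no group)."""
        n = len(self.group)
        return np.column_stack([np.ones(n), self.covariates])


def design_from_phenotypes(
    phenotypes: pd.DataFrame,
    covariate_columns: tuple = ("age", "sex", "education", "mean_fd"),
    group_column: str = "group",
    id_column: str = "subject_id",
) -> Design:
    """Build a Design from a phenotype table (patient = group 1)."""
    covs = phenotypes[list(covariate_columns)].to_numpy(float) if covariate_columns \
        else np.empty((len(phenotypes), 0))
    return Design(phenotypes[group_column].to_numpy(float), covs,
                  list(phenotypes[id_column]))


@dataclass
class EdgeStatResult:
    """Per-edge group z-statistics plus the thresholds in force."""

    z: np.ndarray
    df: int
    cdt_p: float | None = None
    cdt_z: float | None = None
    design_hash: str = ""

    @property
    def sign(self) -> np.ndarray:
        return np.sign(self.z)


@dataclass
class FCCluster:
    """Supra-threshold edges joining two distinct contiguous voxel clusters."""

    edges: list                       # (voxel id i, voxel id j) pairs
    endpoint1: np.ndarray             # voxel ids of the first voxel cluster
    endpoint2: np.ndarray
    n_increased: int
    n_decreased: int
    mean_z: float
    label1: object = None
    label2: object = None
    label1_tie: bool = False
    label2_tie: bool = False
    corrected_p: float | None = None
    extra: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.edges)

    @property
    def sign(self) -> int:
        return 1 if self.mean_z >= 0 else -1


# ---------------------------------------------------------------------------
# GLM

def _t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Map t statistics to z by matching one-sided tail probability."""
    t = np.asarray(t, dtype=float)
    z = -ndtri_exp(stats.t.logsf(np.abs(t), df))
    return np.sign(t) * z


def _group_t(x: np.ndarray, y: np.ndarray, coef: int = 1):
    """Vectorized OLS t-statistics for one coefficient over many outcomes."""
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    pinv = xtx_inv @ x.T
    beta = pinv @ y
    resid = y - x @ beta
    df = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[coef, coef], 1e-300))
    return beta[coef] / se, df


def edge_glm(stack: ConnectomeStack, design: Design) -> EdgeStatResult:
    """Per-edge GLM group comparison.

    Fits ``z_edge ~ intercept + group + covariates`` by least squares for
    every edge; the group t-statistic is converted to a z-statistic by
    one-sided tail-probability matching with the sign preserved.
    """
    if list(design.subject_ids) != list(stack.subject_ids):
        raise ValueError("design subjects do not match stack subjects")
    x = design.matrix
    t, df = _group_t(x, stack.data)
    z = _t_to_z(t, df)
    import hashlib

    h = hashlib.sha256(np.ascontiguousarray(x).tobytes()).hexdigest()[:12]
    return EdgeStatResult(z=z, df=df, design_hash=h)


def cdt_from_p(p_cdt: float, sided: str = "one") -> float:
    """Cluster-defining threshold on the z scale.

    One-sided per tail (applied to |z|): z_cdt is the standard-normal
    upper-tail quantile at ``p_cdt``. ``sided='two'`` uses p/2 per tail.
    """
    if not (0 < p_cdt < 0.5):
        raise ValueError("cdt p must lie in (0, 0.5)")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    p_tail = p_cdt if sided == "one" else p_cdt / 2.0
    return float(stats.norm.isf(p_tail))


# ---------------------------------------------------------------------------
# cluster formation

def _spatial_components(voxel_rows: np.ndarray, voxels: VoxelSet) -> np.ndarray:
    """26-connectivity component id for each requested voxel row."""
    vol = np.zeros(voxels.mask_shape, dtype=bool)
    coords = voxels.coords[voxel_rows]
    vol[tuple(coords.T)] = True
    lab, _n = ndimage.label(vol, structure=_STRUCT_26)
    return lab[tuple(coords.T)]


def form_fc_clusters(
    stat: EdgeStatResult | np.ndarray,
    voxels: VoxelSet,
    z_cdt: float,
    return_intra: bool = False,
):
    """Group supra-threshold edges into FC clusters.

    Edges with |z| >= z_cdt are kept; their endpoint voxels are clustered
    by spatial 26-connectivity; every unordered pair of two *distinct*
    voxel clusters joined by at least one supra-threshold edge becomes an
    FC cluster. Edges internal to a single voxel cluster are excluded
    from FC clusters (returned separately with ``return_intra=True``).
    """
    if z_cdt <= 0:
        raise ValueError("z_cdt must be positive")
    z = stat.z if isinstance(stat, EdgeStatResult) else np.asarray(stat, float)
    n_vox = len(voxels)
    iu, ju = np.triu_indices(n_vox, k=1)
    keep = np.abs(z) >= z_cdt
    out: list[FCCluster] = []
    intra: list[tuple] = []
    if not keep.any():
        return (out, intra) if return_intra else out
    ei, ej, ez = iu[keep], ju[keep], z[keep]

    involved = np.unique(np.concatenate([ei, ej]))
    comp_of = np.full(n_vox, -1, dtype=np.intp)
    comp_of[involved] = _spatial_components(involved, voxels)

    groups: dict[tuple, list[int]] = {}
    for k in range(len(ei)):
        ca, cb = comp_of[ei[k]], comp_of[ej[k]]
        if ca == cb:
            intra.append((int(ei[k]), int(ej[k]), float(ez[k])))
            continue
        key = (min(ca, cb), max(ca, cb))
        groups.setdefault(key, []).append(k)

    for (ca, cb), idx in sorted(groups.items()):
        idx = np.asarray(idx)
        # orient each edge so the first endpoint lies in component ca
        pairs = []
        for k in idx:
            a, b = int(ei[k]), int(ej[k])
            if comp_of[a] != ca:
                a, b = b, a
            pairs.append((a, b))
        e1 = np.unique([p[0] for p in pairs])
        e2 = np.unique([p[1] for p in pairs])
        zz = ez[idx]
        out.append(
            FCCluster(
                edges=[(int(min(a, b)), int(max(a, b))) for a, b in pairs],
                endpoint1=e1,
                endpoint2=e2,
                n_increased=int(np.sum(zz > 0)),
                n_decreased=int(np.sum(zz <= 0)),
                mean_z=float(zz.mean()),
            )
        )
    return (out, intra) if return_intra else out


def _max_cluster_size(t_abs: np.ndarray, iu, ju, t_cdt: float,
                      voxels: VoxelSet, n_vox: int) -> int:
    """Largest FC-cluster size for one (permuted) statistic map."""
    keep = t_abs >= t_cdt
    if not keep.any():
        return 0
    ei, ej = iu[keep], ju[keep]
    involved = np.unique(np.concatenate([ei, ej]))
    comp_of = np.full(n_vox, -1, dtype=np.intp)
    comp_of[involved] = _spatial_components(involved, voxels)
    counts: dict[tuple, int] = {}
    for a, b in zip(comp_of[ei], comp_of[ej]):
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        counts[key] = counts.get(key, 0) + 1
    return max(counts.values(), default=0)


def fwer_cluster_inference(
    stack: ConnectomeStack,
    design: Design,
    z_cdt: float,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[list[FCCluster], dict]:
    """FC clusters with FWER-corrected cluster-size p-values.

    Builds the null distribution of the maximum FC-cluster size by
    Freedman-Lane permutation: the connectivity matrix is residualized
    on the nuisance design, residual rows are permuted, added back to
    the nuisance fit, and the full model is refit and re-clustered.
    corrected p = (1 + #{perm max size >= observed size}) / (1 + n_perm).

    Returns ``(clusters, info)``; ``info`` carries the permutation max
    sizes, the intra-cluster edge log and the thresholds used.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    stat = edge_glm(stack, design)
    clusters, intra = form_fc_clusters(stat, stack.voxels, z_cdt, return_intra=True)

    x = design.matrix
    zmat = design.reduced_matrix
    y = stack.data
    n, p = x.shape
    df = n - p
    # permutation clustering thresholds on the t scale (equivalent to z_cdt)
    t_cdt = float(stats.t.isf(stats.norm.sf(z_cdt), df))
    xtx_inv = np.linalg.inv(x.T @ x)
    pinv = xtx_inv @ x.T
    c_gg = xtx_inv[1, 1]
    beta_red, *_ = np.linalg.lstsq(zmat, y, rcond=None)
    fitted = zmat @ beta_red
    resid = y - fitted

    n_vox = len(stack.voxels)
    iu, ju = np.triu_indices(n_vox, k=1)
    rng = np.random.default_rng(seed)
    max_sizes = np.zeros(n_perm, dtype=np.intp)
    for b in range(n_perm):
        perm = rng.permutation(n)
        ystar = fitted + resid[perm]
        beta = pinv @ ystar
        r = ystar - x @ beta
        sigma2 = np.einsum("ij,ij->j", r, r) / df
        t_abs = np.abs(beta[1]) / np.sqrt(np.maximum(sigma2 * c_gg, 1e-300))
        max_sizes[b] = _max_cluster_size(t_abs, iu, ju, t_cdt, stack.voxels, n_vox)

    for cl in clusters:
        cl.corrected_p = float((1 + np.sum(max_sizes >= cl.size)) / (1 + n_perm))
        cl.extra["significant"] = cl.corrected_p < alpha
    info = {
        "max_sizes": max_sizes,
        "intra_cluster_edges": intra,
        "z_cdt": z_cdt,
        "t_cdt": t_cdt,
        "alpha": alpha,
        "n_perm": n_perm,
        "stat": stat,
    }
    return clusters, info


# ---------------------------------------------------------------------------
# summaries

def measure_of_association(edges, n_voxels: int) -> np.ndarray:
    """Per-voxel count of significant edges incident to that voxel.

    ``edges`` is an iterable of (i, j) voxel-id pairs; the sum of the map
    equals twice the number of edges (handshake identity).
    """
    ma = np.zeros(n_voxels, dtype=np.intp)
    for i, j in edges:
        ma[i] += 1
        ma[j] += 1
    return ma


def _modal_label(labels: np.ndarray) -> tuple[object, bool]:
    labels = labels[labels > 0]
    if labels.size == 0:
        return "NA", False
    vals, counts = np.unique(labels, return_counts=True)
    top = counts.max()
    winners = vals[counts == top]
    return int(winners.min()), len(winners) > 1


def label_cluster(cluster: FCCluster, voxels: VoxelSet) -> tuple:
    """Label each endpoint voxel cluster by its modal atlas label.

    Unlabeled voxels (label 0) count toward no region; ties break to the
    smallest label index and are flagged; an all-unlabeled endpoint gets
    the label "NA". Mutates and returns the cluster's label fields.
    """
    l1, t1 = _modal_label(voxels.labels[cluster.endpoint1])
    l2, t2 = _modal_label(voxels.labels[cluster.endpoint2])
    cluster.label1, cluster.label1_tie = l1, t1
    cluster.label2, cluster.label2_tie = l2, t2
    return l1, l2


def _edge_cols(edges, n_voxels: int) -> np.ndarray:
    cols = []
    for i, j in edges:
        if not (0 <= i < j < n_voxels):
            raise KeyError(f"edge ({i}, {j}) not in a {n_voxels}-voxel stack")
        cols.append(i * (2 * n_voxels - i - 1) // 2 + (j - i - 1))
    return np.asarray(cols, dtype=np.intp)


def cluster_mean_strength(stack: ConnectomeStack, cluster: FCCluster) -> np.ndarray:
    """Per-subject mean Fisher-z over the cluster's edges."""
    cols = _edge_cols(cluster.edges, len(stack.voxels))
    return stack.data[:, cols].mean(axis=1)


def replicate_clusters(
    clusters: list[FCCluster],
    validation_stack: ConnectomeStack,
    validation_design: Design,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Replication test of discovery clusters in an independent cohort.

    Per cluster, the per-subject mean strength in the validation cohort
    is regressed on group + covariates; two-sided p-values are
    Benjamini-Hochberg corrected across clusters; a cluster replicates
    when q < alpha and the validation group effect has the discovery
    cluster's sign.
    """
    from bwaskit.clinical import fdr_bh

    if not clusters:
        return pd.DataFrame(
            columns=["cluster", "size", "beta", "t", "p", "q", "replicated"]
        )
    x = validation_design.matrix
    rows = []
    for ci, cl in enumerate(clusters):
        y = cluster_mean_strength(validation_stack, cl)[:, None]
        t, df = _group_t(x, y)
        t = float(t[0])
        p = float(2 * stats.t.sf(abs(t), df))
        rows.append({"cluster": ci, "size": cl.size, "discovery_sign": cl.sign,
                     "t": t, "p": max(p, np.finfo(float).tiny)})
    tab = pd.DataFrame(rows)
    tab["q"] = fdr_bh(tab["p"].to_numpy())
    tab["replicated"] = (tab["q"] < alpha) & (
        np.sign(tab["t"]) == tab["discovery_sign"]
    )
    return tab
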