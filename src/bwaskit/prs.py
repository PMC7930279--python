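"""Pathway-specific polygenic risk scores and their connectivity associations.

A per-SNP case/control association (allelic 2x2 chi-square) yields
log-odds-ratio weights; genes are clustered by K-means on whole-brain
expression profiles to find the co-expression cluster containing an
anchor gene; the pathway PRS is the log-OR-weighted allele-dosage sum
over the nominally associated SNPs in that cluster. The module also
provides the PRS-connectivity correlation analyses: per-cluster partial
correlations, a correlation-set contrast between illness stages, a
mean-FC permutation test, and the unfiltered-panel specificity contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from bwaskit.clinical import partial_correlation, permutation_pvalue

__all__ = [
    "SnpAssociation",
    "PRSModel",
    "GeneCluster",
    "snp_association",
    "select_snps",
    "compute_prs",
    "kmeans_gene_clusters",
    "prs_fc_correlation",
    "compare_correlation_sets",
    "mean_fc_prs_test",
    "unfiltered_prs_contrast",
]


@dataclass
class SnpAssociation:
    snp_id: str
    gene: str
    effect_allele: str
    odds_ratio: float
    log_or: float
    p_value: float
    table: np.ndarray            # [[case ALT, case REF], [ctrl ALT, ctrl REF]]
    corrected: bool = False      # Haldane-Anscombe 0.5 applied


@dataclass
class PRSModel:
    snp_ids: list
    weights: np.ndarray          # log odds ratios, signed
    p_threshold: float
    gene_cluster: list = field(default_factory=list)
    scores: np.ndarray | None = None


@dataclass
class GeneCluster:
    assignments: dict            # gene -> cluster id
    anchor_gene: str
    k: int
    seed: int

    @property
    def anchor_members(self) -> list:
        cid = self.assignments[self.anchor_gene]
        return [g for g, c in self.assignments.items() if c == cid]


def snp_association(
    dosages: np.ndarray,
    case_labels: np.ndarray,
    snp_table: pd.DataFrame,
    backend: str = "allelic",
) -> tuple[list[SnpAssociation], list[str]]:
    """Per-SNP case/control association on allele counts.

    Default backend: 2x2 allele-count table (effect = ALT allele), odds
    ratio by cross-product with the Haldane-Anscombe 0.5 correction when
    any cell is zero, and a 1-df chi-square p with continuity correction.
    ``backend='logistic'`` instead fits a per-SNP logistic regression of
    case status on dosage (sensitivity analysis). Monomorphic SNPs are
    excluded and returned as warnings.
    """
    dos = np.asarray(dosages)
    labels = np.asarray(case_labels).astype(int)
    if set(np.unique(dos)) - {0, 1, 2}:
        raise ValueError("dosages must be in {0, 1, 2}")
    if len(np.unique(labels)) < 2:
        raise ValueError("both cases and controls required")
    case = labels == 1
    out, warnings = [], []
    for s, row in enumerate(snp_table.itertuples(index=False)):
        alt_case = int(dos[case, s].sum())
        alt_ctrl = int(dos[~case, s].sum())
        ref_case = int(2 * case.sum() - alt_case)
        ref_ctrl = int(2 * (~case).sum() - alt_ctrl)
        table = np.array([[alt_case, ref_case], [alt_ctrl, ref_ctrl]])
        if table.sum(axis=0).min() == 0:  # monomorphic: one allele absent
            warnings.append(row.snp_id)
            continue
        corrected = (table == 0).any()
        t = table + 0.5 if corrected else table.astype(float)
        orr = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
        if backend == "allelic":
            _chi2, p, _df, _exp = stats.chi2_contingency(table, correction=True)
        elif backend == "logistic":
            import statsmodels.api as sm

            x = sm.add_constant(dos[:, s].astype(float))
            fit = sm.Logit(labels, x).fit(disp=0)
            p = float(fit.pvalues[1])
        else:
            raise ValueError(f"unknown backend {backend!r}")
        out.append(
            SnpAssociation(
                snp_id=row.snp_id, gene=row.gene, effect_allele="ALT",
                odds_ratio=float(orr), log_or=float(np.log(orr)),
                p_value=float(p), table=table, corrected=bool(corrected),
            )
        )
    return out, warnings


def select_snps(
    associations: list[SnpAssociation],
    genes_in_cluster,
    p_threshold: float = 0.05,
) -> list[str]:
    """SNPs in the gene cluster with association p below the threshold."""
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must lie in (0, 1]")
    cluster = set(genes_in_cluster)
    return [a.snp_id for a in associations
            if a.gene in cluster and a.p_value < p_threshold]


def build_prs_model(
    associations: list[SnpAssociation],
    snp_ids: list[str],
    p_threshold: float,
    gene_cluster=(),
) -> PRSModel:
    by_id = {a.snp_id: a for a in associations}
    weights = np.array([by_id[s].log_or for s in snp_ids])
    return PRSModel(list(snp_ids), weights, p_threshold, list(gene_cluster))


def compute_prs(dosages: np.ndarray, model: PRSModel,
                snp_table: pd.DataFrame) -> np.ndarray:
    """Per-subject PRS: weighted dosage sum with log-OR weights.

    score_i = sum_s log(OR_s) * dosage_{i,s} over the model's SNPs; an
    empty model yields all-zero scores (a warning is the caller's
    responsibility via select_snps).
    """
    cols = {sid: j for j, sid in enumerate(snp_table["snp_id"])}
    missing = [s for s in model.snp_ids if s not in cols]
    if missing:
        raise KeyError(f"model SNPs absent from dosage matrix: {missing}")
    if not model.snp_ids:
        return np.zeros(len(dosages))
    idx = [cols[s] for s in model.snp_ids]
    scores = np.asarray(dosages, float)[:, idx] @ model.weights
    model.scores = scores
    return scores


def kmeans_gene_clusters(
    expression: pd.DataFrame,
    k: int = 5,
    anchor_gene: str = "FOXP2",
    n_restarts: int = 50,
    seed: int = 0,
) -> GeneCluster:
    """K-means co-expression clustering of genes over brain regions.

    Rows (genes) are z-scored so clustering reflects profile shape, then
    partitioned by best-of-``n_restarts`` K-means on within-cluster sum
    of squares. Deterministic given ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(expression):
        raise ValueError("k cannot exceed the number of genes")
    if anchor_gene not in expression.index:
        raise KeyError(f"anchor gene {anchor_gene!r} not in expression matrix")
    x = expression.to_numpy(float)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    xs = (x - x.mean(axis=1, keepdims=True)) / sd
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    lab = km.fit_predict(xs)
    return GeneCluster(dict(zip(expression.index, lab.tolist())),
                       anchor_gene, k, seed)


def prs_fc_correlation(
    scores: np.ndarray,
    cluster_strengths: pd.DataFrame,
    covariates: np.ndarray | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Partial correlation of the PRS with each FC cluster's strength.

    Unadjusted by default (pass ``covariates`` to adjust); permutation
    p-values per cluster. Patients only by convention of the caller.
    """
    scores = np.asarray(scores, float)
    if scores.std() == 0:
        raise ValueError("PRS is constant (no selected SNPs?)")
    rows = []
    for ci, col in enumerate(cluster_strengths.columns):
        r, p = permutation_pvalue(
            scores, cluster_strengths[col].to_numpy(float), covariates,
            n_perm=n_perm, seed=seed + ci,
        )
        rows.append({"cluster": col, "r": r, "p": p})
    return pd.DataFrame(rows)


def compare_correlation_sets(
    r_set_a, r_set_b, mode: str = "absolute"
) -> dict:
    """Two-sample t contrast of two sets of correlation coefficients.

    ``mode`` transforms the r values first: 'raw' (none), 'absolute'
    (|r|), or 'fisher_z' (atanh). Reports both the pooled-variance and
    Welch t with one-sided p for mean(A) > mean(B).
    """
    a = np.asarray(r_set_a, float)
    b = np.asarray(r_set_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each correlation set needs >= 2 values")
    if mode == "absolute":
        a, b = np.abs(a), np.abs(b)
    elif mode == "fisher_z":
        a, b = np.arctanh(a), np.arctanh(b)
    elif mode != "raw":
        raise ValueError("mode must be raw, absolute or fisher_z")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va + vb == 0:
        if a.mean() == b.mean():
            return {"t_pooled": 0.0, "df_pooled": a.size + b.size - 2,
                    "p_pooled": 0.5, "t_welch": 0.0,
                    "df_welch": a.size + b.size - 2, "p_welch": 0.5,
                    "mean_a": float(a.mean()), "mean_b": float(b.mean())}
        raise ValueError("zero pooled variance with unequal means")
    t_p, p_p = stats.ttest_ind(a, b, equal_var=True, alternative="greater")
    t_w, p_w = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    df_p = a.size + b.size - 2
    df_w = (va / a.size + vb / b.size) ** 2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    return {
        "t_pooled": float(t_p), "df_pooled": int(df_p), "p_pooled": float(p_p),
        "t_welch": float(t_w), "df_welch": float(df_w), "p_welch": float(p_w),
        "mean_a": float(a.mean()), "mean_b": float(b.mean()),
    }


def mean_fc_prs_test(
    scores: np.ndarray,
    stack,
    significant_edges,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Correlation between PRS and mean altered connectivity, permutation p.

    Per subject, the mean Fisher-z over the union of significant edges;
    Pearson r against the PRS; one-sided p (r* >= r_observed) by
    shuffling the PRS.
    """
    from bwaskit.bwas import _edge_cols

    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    edges = sorted(set(significant_edges))
    if not edges:
        raise ValueError("empty significant edge set")
    cols = _edge_cols(edges, len(stack.voxels))
    mean_fc = stack.data[:, cols].mean(axis=1)
    scores = np.asarray(scores, float)
    r_obs = partial_correlation(scores, mean_fc)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        r_perm = partial_correlation(scores[rng.permutation(len(scores))], mean_fc)
        if r_perm >= r_obs - 1e-12:
            count += 1
    return r_obs, float((1 + count) / (1 + n_perm))


def unfiltered_prs_contrast(
    dosages: np.ndarray,
    associations: list[SnpAssociation],
    cluster_genes,
    cluster_strengths: pd.DataFrame,
    snp_table: pd.DataFrame,
    p_threshold: float = 0.05,
    n_perm: int = 2000,
    seed: int = 0,
) -> dict:
    """Specificity contrast: co-expression-cluster PRS vs unfiltered-panel PRS.

    Builds both PRS variants (SNPs restricted to the anchor co-expression
    cluster's genes vs all panel genes, both at the same association p
    threshold), computes the mean |r| against the FC-cluster strengths
    for each, and a permutation p for the difference obtained by
    permuting subjects of the unrestricted score.
    """
    all_genes = sorted({a.gene for a in associations})
    ids_cluster = select_snps(associations, cluster_genes, p_threshold)
    ids_all = select_snps(associations, all_genes, p_threshold)
    if not ids_cluster or not ids_all:
        raise ValueError("no SNPs selected for one of the PRS variants")
    m_cluster = build_prs_model(associations, ids_cluster, p_threshold, cluster_genes)
    m_all = build_prs_model(associations, ids_all, p_threshold, all_genes)
    s_cluster = compute_prs(dosages, m_cluster, snp_table)
    s_all = compute_prs(dosages, m_all, snp_table)

    def _mean_abs_r(scores: np.ndarray) -> float:
        return float(np.mean([
            abs(partial_correlation(scores, cluster_strengths[c].to_numpy(float)))
            for c in cluster_strengths.columns
        ]))

    obs_cluster = _mean_abs_r(s_cluster)
    obs_all = _mean_abs_r(s_all)
    diff = obs_cluster - obs_all
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        # null: cluster restriction carries no extra signal -> a relabeled
        # cluster score should beat the unfiltered score as often as not
        perm_diff = _mean_abs_r(s_cluster[rng.permutation(len(s_cluster))]) - obs_all
        if perm_diff >= diff - 1e-12:
            count += 1
    return {
        "mean_abs_r_cluster": obs_cluster,
        "mean_abs_r_unfiltered": obs_all,
        "difference": diff,
        "p_perm": float((1 + count) / (1 + n_perm)),
        "n_snps_cluster": len(ids_cluster),
        "n_snps_unfiltered": len(ids_all),
    }
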