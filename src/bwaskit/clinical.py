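"""Symptom-connectivity associations and illness-duration stratification.

Partial correlations between FC-cluster strength and symptom scores with
permutation p-values and Benjamini-Hochberg FDR; median split of illness
duration with stage-specific cluster analyses (each patient subgroup vs
all controls).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from bwaskit.bwas import Design, FCCluster, fwer_cluster_inference
from bwaskit.connectome import ConnectomeStack

__all__ = [
    "partial_correlation",
    "permutation_pvalue",
    "fdr_bh",
    "median_split",
    "stage_bwas",
    "association_table",
]


def _residualize(v: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = len(v)
    if covariates is None or np.size(covariates) == 0:
        c = np.ones((n, 1))
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        c = np.column_stack([np.ones(n), c])
    beta, *_ = np.linalg.lstsq(c, v, rcond=None)
    return v - c @ beta


def partial_correlation(x, y, covariates=None) -> float:
    """Pearson correlation of x and y after removing covariates.

    Both variables are residualized on the covariates plus an intercept;
    with no covariates this reduces to the plain Pearson r.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and aligned")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero residual variance: constant input")
    rx = _residualize(x, covariates)
    ry = _residualize(y, covariates)
    sx, sy = np.sqrt(rx @ rx), np.sqrt(ry @ ry)
    # a variable numerically absorbed by the covariates carries no signal
    if sx <= 1e-10 * x.std() * np.sqrt(len(x)) or \
            sy <= 1e-10 * y.std() * np.sqrt(len(y)):
        return 0.0
    return float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))


def permutation_pvalue(x, y, covariates=None, n_perm: int = 10_000,
                       seed: int = 0) -> tuple[float, float]:
    """Two-sided permutation p for the partial correlation of x and y.

    Freedman-Lane style: the covariate-residualized y is permuted and
    re-correlated with residualized x; p = (1 + #{|r*| >= |r|}) / (1 + n_perm).
    Returns ``(r_observed, p)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero residual variance: constant input")
    rx = _residualize(x, covariates)
    ry = _residualize(y, covariates)
    sx, sy = np.sqrt(rx @ rx), np.sqrt(ry @ ry)
    if sx == 0 or sy == 0:
        raise ValueError("zero residual variance")
    r_obs = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    rng = np.random.default_rng(seed)
    rxu = rx / sx
    count = 0
    for _ in range(n_perm):
        ryp = ry[rng.permutation(len(ry))]
        r_perm = (rxu @ ryp) / sy
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            count += 1
    return r_obs, float((1 + count) / (1 + n_perm))


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a nonempty 1-D array")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def median_split(durations) -> tuple[list, list, float]:
    """Split patient indices at the median illness duration.

    Returns ``(short_idx, long_idx, median)``; durations at or below the
    sample median (midpoint convention for even n) go to the short group.
    """
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise ValueError("empty duration vector")
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise ValueError("durations must be positive and finite")
    med = float(np.median(d))
    short = np.flatnonzero(d <= med).tolist()
    long = np.flatnonzero(d > med).tolist()
    return short, long, med


def stage_bwas(
    stack: ConnectomeStack,
    phenotypes: pd.DataFrame,
    short_ids: list,
    long_ids: list,
    z_cdt: float,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    covariate_columns: tuple = ("age", "sex", "education", "mean_fd"),
) -> dict:
    """Stage-specific cluster analysis: each patient subgroup vs all controls.

    ``short_ids``/``long_ids`` are patient subject ids; all control
    subjects (group 0) enter both comparisons. Each comparison runs the
    full FWER cluster-size inference at the subgroup cluster-defining
    threshold ``z_cdt``.
    """
    from bwaskit.bwas import design_from_phenotypes

    if len(short_ids) == 0 or len(long_ids) == 0:
        raise ValueError("both duration subgroups must be nonempty")
    controls = list(phenotypes.loc[phenotypes["group"] == 0, "subject_id"])
    out = {}
    for name, ids in (("short", list(short_ids)), ("long", list(long_ids))):
        subj = ids + controls
        ph = phenotypes.set_index("subject_id").loc[subj].reset_index()
        sub = stack.subset(subj)
        design = design_from_phenotypes(ph, covariate_columns)
        clusters, info = fwer_cluster_inference(
            sub, design, z_cdt, n_perm=n_perm, seed=seed, alpha=alpha
        )
        out[name] = {"clusters": clusters, "info": info}
    return out


def association_table(
    strengths: pd.DataFrame,
    scores: np.ndarray,
    covariates: np.ndarray | None,
    n_perm: int = 10_000,
    seed: int = 0,
    labels: list[tuple] | None = None,
) -> pd.DataFrame:
    """Cluster-by-cluster symptom association table.

    ``strengths`` has one column per FC cluster (per-subject mean
    strength) aligned with ``scores``. Each cluster gets a partial r, a
    permutation p and a BH-FDR q; mirrors a per-cluster correlation
    table with region labels when ``labels`` is given.
    """
    rows = []
    for ci, col in enumerate(strengths.columns):
        r, p = permutation_pvalue(
            strengths[col].to_numpy(float), scores, covariates,
            n_perm=n_perm, seed=seed + ci,
        )
        row = {"cluster": col, "r": r, "p": p}
        if labels is not None:
            row["region1"], row["region2"] = labels[ci]
        rows.append(row)
    tab = pd.DataFrame(rows)
    tab["q"] = fdr_bh(tab["p"].to_numpy())
    return tab
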