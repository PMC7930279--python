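"""Per-subject voxel-level functional connectivity.

Turns cleaned (or raw synthetic) voxel time series into Fisher-z
connectivity edge vectors, after motion-based subject exclusion,
band-pass filtering and nuisance regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

# atanh(1 - 1e-7) ~ 8.4; keeps z finite for numerically perfect correlations
_R_CLAMP = 1.0 - 1e-7


@dataclass
class VoxelSet:
    """A fixed set of voxels inside a mask.

    Attributes
    ----------
    ids : (V,) int array of voxel identifiers (0-based, unique).
    coords : (V, 3) int array of 0-based grid coordinates.
    labels : (V,) int array of atlas labels; 0 means unlabeled.
    mask_shape : 3-tuple, the grid extents.
    """

    ids: np.ndarray
    coords: np.ndarray
    labels: np.ndarray
    mask_shape: tuple

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.intp)
        self.coords = np.asarray(self.coords, dtype=np.intp)
        self.labels = np.asarray(self.labels, dtype=np.intp)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (V, 3)")
        if len({tuple(c) for c in self.coords}) != len(self.coords):
            raise ValueError("voxel coordinates must be unique")
        if np.any(self.labels < 0):
            raise ValueError("atlas labels must be >= 0")
        if np.any(self.coords < 0) or np.any(self.coords >= np.array(self.mask_shape)):
            raise ValueError("voxel coordinates fall outside the mask shape")

    def __len__(self) -> int:
        return len(self.ids)


def edge_index(n_voxels: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle (i < j) edge index over ``n_voxels`` voxels."""
    return np.triu_indices(n_voxels, k=1)


@dataclass
class ConnectomeStack:
    """Subjects x edges matrix of Fisher-z connectivity values.

    Edges are all unordered voxel pairs (i < j) over ``voxels``, in
    ``numpy.triu_indices`` order. ``data[s, e]`` is subject ``s``'s
    Fisher-z value on edge ``e``.
    """

    subject_ids: list
    voxels: VoxelSet
    data: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n_edges = len(self.voxels) * (len(self.voxels) - 1) // 2
        if self.data.ndim != 2 or self.data.shape != (len(self.subject_ids), n_edges):
            raise ValueError(
                f"data must be (n_subjects={len(self.subject_ids)}, "
                f"n_edges={n_edges}); got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("connectivity values must be finite")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_edges(self) -> int:
        return self.data.shape[1]

    @property
    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        return edge_index(len(self.voxels))

    def subset(self, subject_ids: Sequence) -> "ConnectomeStack":
        """Row subset by subject id, preserving the requested order."""
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in subject_ids if s not in pos]
        if missing:
            raise KeyError(f"unknown subject ids: {missing}")
        rows = [pos[s] for s in subject_ids]
        return ConnectomeStack(
            list(subject_ids), self.voxels, self.data[rows], dict(self.provenance)
        )


def exclude_high_motion(
    phenotypes: pd.DataFrame,
    fd_threshold: float = 0.5,
    fd_column: str = "mean_fd",
    id_column: str = "subject_id",
) -> list:
    """Subjects retained after the mean framewise-displacement cut.

    Subjects whose mean FD strictly exceeds ``fd_threshold`` (default
    0.5 mm) are removed; input order is preserved. Missing FD values are
    an error (they cannot be assumed low-motion).
    """
    if fd_threshold <= 0:
        raise ValueError("fd_threshold must be positive")
    if len(phenotypes) == 0:
        return []
    if fd_column not in phenotypes.columns:
        raise KeyError(f"phenotype table lacks column {fd_column!r}")
    fd = phenotypes[fd_column].to_numpy(dtype=float)
    bad = ~np.isfinite(fd)
    if bad.any():
        who = list(phenotypes.loc[bad, id_column])
        raise ValueError(f"missing mean FD for subjects: {who}")
    keep = fd <= fd_threshold
    return list(phenotypes.loc[keep, id_column])


def bandpass_and_regress(
    series: np.ndarray,
    confounds: np.ndarray | None,
    low_hz: float,
    high_hz: float,
    tr: float,
) -> np.ndarray:
    """Band-pass filter and regress confounds from voxel time series.

    ``series`` is time x voxels. Both the signal and the confound columns
    are passed through a zero-phase frequency-mask filter retaining
    [low_hz, high_hz] (DC removed, so outputs have ~zero mean); the
    filtered confounds plus an intercept are then regressed out by least
    squares. Filtering the confounds first keeps the operation a true
    projection, so cleaning is idempotent.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 2:
        raise ValueError("series must be 2-D (time x voxels)")
    t = y.shape[0]
    if t < 32:
        raise ValueError("need at least 32 timepoints")
    nyquist = 0.5 / tr
    if not (0 <= low_hz < high_hz < nyquist):
        raise ValueError(
            f"band must satisfy 0 <= low < high < Nyquist ({nyquist:.4g} Hz)"
        )

    freqs = np.fft.rfftfreq(t, d=tr)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    keep[0] = False  # always drop DC

    def _filt(x: np.ndarray) -> np.ndarray:
        spec = np.fft.rfft(x, axis=0)
        spec[~keep] = 0.0
        return np.fft.irfft(spec, n=t, axis=0)

    y = _filt(y)
    if confounds is not None and np.size(confounds) > 0:
        c = np.asarray(confounds, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        if c.shape[0] != t:
            raise ValueError("confounds and series disagree on time length")
        c = _filt(c)
        # drop all-zero columns produced by filtering constant confounds
        nz = np.ptp(c, axis=0) > 0
        c = c[:, nz]
        if c.shape[1]:
            rank = np.linalg.matrix_rank(c)
            if rank < c.shape[1]:
                raise ValueError(
                    f"confound matrix is rank deficient after filtering "
                    f"(rank {rank} < {c.shape[1]} columns)"
                )
            beta, *_ = np.linalg.lstsq(c, y, rcond=None)
            y = y - c @ beta
    return y


def fc_matrix(series: np.ndarray) -> np.ndarray:
    """Fisher-z connectivity over all unordered voxel pairs.

    Pearson correlations between every pair of columns of ``series``
    (time x voxels), clamped to +/-(1 - 1e-7) and arctanh-transformed;
    returned in upper-triangle (i < j) edge order.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("series must be time x voxels with >= 3 timepoints")
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance voxels: {dead.tolist()}")
    r = np.corrcoef(x, rowvar=False)
    iu, ju = np.triu_indices(x.shape[1], k=1)
    rv = np.clip(r[iu, ju], -_R_CLAMP, _R_CLAMP)
    return np.arctanh(rv)


def connectome_stack(
    series_per_subject: Sequence[np.ndarray],
    subject_ids: Sequence,
    voxels: VoxelSet,
    confounds_per_subject: Sequence[np.ndarray | None] | None = None,
    low_hz: float | None = None,
    high_hz: float | None = None,
    tr: float | None = None,
) -> ConnectomeStack:
    """Build a ConnectomeStack, optionally cleaning each subject first.

    When ``low_hz``/``high_hz``/``tr`` are given each subject's series is
    passed through :func:`bandpass_and_regress` before correlation.
    """
    clean = low_hz is not None
    rows = []
    for i, s in enumerate(series_per_subject):
        x = s
        if clean:
            conf = None
            if confounds_per_subject is not None:
                conf = confounds_per_subject[i]
            x = bandpass_and_regress(x, conf, low_hz, high_hz, tr)
        rows.append(fc_matrix(x))
    prov = {"filter_band_hz": (low_hz, high_hz) if clean else None, "tr": tr}
    return ConnectomeStack(list(subject_ids), voxels, np.vstack(rows), prov)
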