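"""Network-level functional connectivity.

Per-network mean time courses, Fisher-z Pearson connectivity matrices, and
white-/gray-matter network correspondence (best-matching gray-matter
network per white-matter network, reported only when r reaches a
threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .clustering import Parcellation
from .mask import GroupMask

__all__ = [
    "NetworkTimeCourses",
    "FCMatrix",
    "network_timecourses",
    "fc_matrix",
    "gm_correspondence",
    "gm_correspondence_cohort",
]

#: |r| is clipped here before atanh so z stays finite for group statistics.
R_CLIP = 1.0 - 1e-7


@dataclass
class NetworkTimeCourses:
    """K x T matrix of per-network mean BOLD time courses."""

    series: np.ndarray
    network_ids: np.ndarray

    @property
    def k(self) -> int:
        return int(self.series.shape[0])

    @property
    def t(self) -> int:
        return int(self.series.shape[1])


@dataclass
class FCMatrix:
    """Symmetric network FC: Pearson r and Fisher z, diagonal masked as NaN."""

    r: np.ndarray
    z: np.ndarray
    network_ids: np.ndarray

    @property
    def k(self) -> int:
        return int(self.r.shape[0])

    def edge_vector(self) -> tuple[np.ndarray, np.ndarray]:
        """(z values, edge index pairs) over the K(K-1)/2 upper-triangle edges."""
        iu, ju = np.triu_indices(self.k, 1)
        return self.z[iu, ju], np.column_stack([iu, ju])


def network_timecourses(
    bold: np.ndarray, parcellation: Parcellation, mask: GroupMask
) -> NetworkTimeCourses:
    """Unweighted mean series over each network's voxels."""
    if parcellation.labels.shape[0] != mask.n_voxels:
        raise ValueError("parcellation is not indexed on this mask's voxel order")
    x = mask.extract_series(bold)
    # label 0 marks voxels excluded from clustering (zero-variance policy)
    ids = np.array(sorted(i for i in np.unique(parcellation.labels).tolist() if i > 0))
    if len(ids) == 0:
        raise ValueError("parcellation has no networks")
    series = np.empty((len(ids), x.shape[1]))
    for row, net in enumerate(ids):
        members = parcellation.labels == net
        if not members.any():
            raise ValueError(f"network {net} has no voxels")
        series[row] = x[members].mean(axis=0)
    return NetworkTimeCourses(series=series, network_ids=ids)


def fc_matrix(tc: NetworkTimeCourses) -> FCMatrix:
    """Pearson r between all network pairs, Fisher z off-diagonal.

    |r| is clipped at 1 - 1e-7 before atanh (with a warning) so that
    perfectly collinear series give a large finite z instead of infinity.
    Constant series are a hard error naming the offending network.
    """
    if tc.t < 3:
        raise ValueError("need at least 3 time points")
    sd = tc.series.std(axis=1)
    tol = 1e-10 * (np.abs(tc.series).max(axis=1) + 1e-300)
    if np.any(sd <= tol):
        bad = tc.network_ids[sd <= tol].tolist()
        raise ValueError(f"constant time course for network(s) {bad}")
    r = np.corrcoef(tc.series)
    off = ~np.eye(tc.k, dtype=bool)
    if np.any(np.abs(r[off]) >= R_CLIP):
        warnings.warn("|r| at the clip bound 1 - 1e-7; z saturated", stacklevel=2)
    r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(r, np.nan)
    np.fill_diagonal(z, np.nan)
    return FCMatrix(r=r, z=z, network_ids=tc.network_ids)


def gm_correspondence(
    wm_tc: NetworkTimeCourses,
    gm_tc: NetworkTimeCourses,
    report_threshold: float = 0.4,
) -> dict:
    """Best-matching gray-matter network per white-matter network.

    Returns ``{wm_id: (gm_id, r) | None}``; a white-matter network whose
    best correlation falls below ``report_threshold`` maps to ``None``
    (reported as "–" in tables).
    """
    if wm_tc.t != gm_tc.t:
        raise ValueError("time course lengths differ")
    cross = _cross_correlation(wm_tc.series, gm_tc.series)
    return _best_matches(cross, wm_tc.network_ids, gm_tc.network_ids, report_threshold)


def gm_correspondence_cohort(
    wm_tcs: list,
    gm_tcs: list,
    report_threshold: float = 0.4,
) -> dict:
    """Correspondence from subject-wise correlations averaged over the cohort."""
    if len(wm_tcs) != len(gm_tcs) or not wm_tcs:
        raise ValueError("need matching non-empty lists of time courses")
    cross = np.mean(
        [_cross_correlation(w.series, g.series) for w, g in zip(wm_tcs, gm_tcs)],
        axis=0,
    )
    return _best_matches(
        cross, wm_tcs[0].network_ids, gm_tcs[0].network_ids, report_threshold
    )


def _cross_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlation between two series matrices."""

    def standardize(x):
        xc = x - x.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(xc, axis=1, keepdims=True)
        if np.any(norm == 0):
            raise ValueError("constant time course")
        return xc / norm

    return standardize(a) @ standardize(b).T


def _best_matches(cross, wm_ids, gm_ids, threshold) -> dict:
    out = {}
    for row, wm_id in enumerate(wm_ids):
        best = int(np.argmax(cross[row]))
        r = float(cross[row, best])
        out[int(wm_id)] = (int(gm_ids[best]), r) if r >= threshold else None
    return out
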