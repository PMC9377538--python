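"""Group-level white-matter analysis mask.

Subject tissue-probability maps are reduced to hard labels (max probability),
labels are averaged across the cohort, and voxels classified as the target
tissue in strictly more than ``threshold`` of subjects form the group mask.
An exclusion volume (e.g. a subcortical atlas mask supplied as input) can be
subtracted afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TISSUE_CODES",
    "GroupMask",
    "subject_tissue_label",
    "group_mask",
    "apply_exclusion",
]

#: Integer codes used in hard tissue-label volumes. 0 means "none".
TISSUE_CODES = {"WM": 1, "GM": 2, "CSF": 3}


def _ordered_index(mask: np.ndarray) -> np.ndarray:
    """In-mask voxel coordinates as an (V, 3) int array in fixed order.

    Order is ascending by (z, y, x): z varies slowest, x fastest.  Every
    downstream structure (correlation profiles, parcellations, network
    time courses) is indexed on this ordering.
    """
    ix, iy, iz = np.nonzero(mask)
    order = np.lexsort((ix, iy, iz))
    return np.column_stack([ix[order], iy[order], iz[order]])


@dataclass
class GroupMask:
    """Boolean group-level mask plus its canonical voxel ordering."""

    mask: np.ndarray
    fraction_map: np.ndarray
    threshold: float
    voxel_index: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.fraction_map = np.asarray(self.fraction_map, dtype=np.float32)
        if self.mask.shape != self.fraction_map.shape:
            raise ValueError("mask and fraction_map shapes differ")
        self.voxel_index = _ordered_index(self.mask)

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_index.shape[0])

    def extract_series(self, bold: np.ndarray) -> np.ndarray:
        """(V, T) matrix of in-mask voxel time series in canonical order."""
        vi = self.voxel_index
        return np.asarray(bold[vi[:, 0], vi[:, 1], vi[:, 2], :], dtype=np.float64)


def subject_tissue_label(tissue_probs) -> np.ndarray:
    """Hard tissue labels from (WM, GM, CSF) probability volumes.

    The label is the tissue of maximum probability; ties are broken by the
    fixed precedence WM > GM > CSF so the result is deterministic.  Voxels
    where all three probabilities are zero get label 0 ("none").
    """
    wm, gm, csf = (np.asarray(p, dtype=np.float64) for p in tissue_probs)
    if not (wm.shape == gm.shape == csf.shape):
        raise ValueError("tissue probability volumes have mismatched shapes")
    stacked = np.stack([wm, gm, csf], axis=0)
    if stacked.min() < 0 or stacked.max() > 1:
        raise ValueError("tissue probabilities must lie in [0, 1]")
    labels = np.argmax(stacked, axis=0).astype(np.int16) + 1
    labels[stacked.sum(axis=0) == 0] = 0
    return labels


def group_mask(subject_labels, tissue: str = "WM", threshold: float = 0.6) -> GroupMask:
    """Group mask of voxels labelled ``tissue`` in > ``threshold`` of subjects.

    The comparison is strictly greater-than: a voxel at exactly the
    threshold fraction is excluded.
    """
    if tissue not in TISSUE_CODES:
        raise ValueError(f"unknown tissue {tissue!r}")
    subject_labels = [np.asarray(lab) for lab in subject_labels]
    if len(subject_labels) < 2:
        raise ValueError("need at least 2 subjects for a group mask")
    shape = subject_labels[0].shape
    if any(lab.shape != shape for lab in subject_labels):
        raise ValueError("subject label volumes have mismatched shapes")
    code = TISSUE_CODES[tissue]
    fraction = np.mean([lab == code for lab in subject_labels], axis=0)
    return GroupMask(mask=fraction > threshold, fraction_map=fraction, threshold=threshold)


def apply_exclusion(mask: GroupMask, exclusion: np.ndarray) -> GroupMask:
    """Remove voxels inside a boolean exclusion volume; rebuild the index."""
    exclusion = np.asarray(exclusion, dtype=bool)
    if exclusion.shape != mask.mask.shape:
        raise ValueError("exclusion volume shape differs from mask")
    return GroupMask(
        mask=mask.mask & ~exclusion,
        fraction_map=mask.fraction_map,
        threshold=mask.threshold,
    )
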