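"""Voxel-profile clustering of white-matter BOLD signal.

Each white-matter voxel is described by its vector of Pearson correlations
with a deterministic ~1-in-4 "interchanging grid" subsample of mask voxels
(the nodes).  Profiles are averaged within and then across groups, and
voxels are clustered with correlation-distance k-means (row
standardisation makes squared Euclidean distance affinely equivalent to
1 - r, so a well-tested Euclidean optimiser does the work).

The number of networks K is selected by fold stability: node columns are
split into near-equal random folds, each fold is clustered independently
at every candidate K, and agreement between fold pairs is measured by the
Dice coefficient of the voxel co-assignment relations.  The selected K is
the largest one whose mean Dice exceeds a stability threshold.

Networks are finally tagged as superficial / middle / deep layers by their
mean Euclidean distance to gray matter.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .mask import GroupMask

__all__ = [
    "CorrelationProfile",
    "Parcellation",
    "StabilityCurve",
    "interchanging_grid_subsample",
    "correlation_profile",
    "average_profiles",
    "kmeans_correlation",
    "dice_coassignment",
    "stability_analysis",
    "select_k",
    "assign_layers",
]

LAYERS = ("superficial", "middle", "deep")


@dataclass
class CorrelationProfile:
    """V x N matrix of voxel-to-node Pearson correlations."""

    values: np.ndarray
    voxel_index: np.ndarray  # (V, 3)
    node_index: np.ndarray  # (N, 3), subset of voxel_index
    invalid_voxels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_voxels(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_nodes(self) -> int:
        return int(self.values.shape[1])


@dataclass
class Parcellation:
    """Voxel -> network labelling on the group-mask voxel order."""

    labels: np.ndarray  # (V,), values 1..k
    k: int
    voxel_index: np.ndarray
    layer: dict = field(default_factory=dict)  # network id -> layer name
    mean_gm_distance: dict = field(default_factory=dict)  # network id -> mm

    def network_sizes(self) -> dict:
        ids, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    def label_volume(self, shape: tuple) -> np.ndarray:
        vol = np.zeros(shape, dtype=np.int32)
        vi = self.voxel_index
        vol[vi[:, 0], vi[:, 1], vi[:, 2]] = self.labels
        return vol


@dataclass
class StabilityCurve:
    """Mean fold-pair Dice agreement per candidate K."""

    k_values: np.ndarray
    mean_dice: np.ndarray
    per_pair_dice: list  # per K: list of fold-pair Dice values

    def as_dict(self) -> dict:
        return {int(k): float(d) for k, d in zip(self.k_values, self.mean_dice)}


def interchanging_grid_subsample(mask: GroupMask) -> np.ndarray:
    """Deterministic checkerboard node selection.

    On even z-slices keep in-mask voxels with even x and y; on odd slices
    keep those with odd x and y — roughly one voxel in four, alternating
    position between consecutive slices.  Returns positions of the selected
    nodes within ``mask.voxel_index``.
    """
    vi = mask.voxel_index
    if len(vi) == 0:
        raise ValueError("empty mask")
    x, y, z = vi[:, 0], vi[:, 1], vi[:, 2]
    parity = z % 2
    sel = (x % 2 == parity) & (y % 2 == parity)
    nodes = np.nonzero(sel)[0]
    if len(nodes) == 0:
        raise ValueError("interchanging grid selected no nodes")
    return nodes


def correlation_profile(
    bold: np.ndarray, mask: GroupMask, nodes: np.ndarray
) -> CorrelationProfile:
    """Pearson correlation of every in-mask voxel with every node.

    Zero-variance voxel series cannot carry a correlation; their rows (and
    node columns, where a node is itself degenerate) are set to 0 and the
    voxels recorded in ``invalid_voxels`` so callers exclude them from
    clustering.
    """
    t = bold.shape[-1]
    if t < 3:
        raise ValueError("need at least 3 time points")
    x = mask.extract_series(bold)  # (V, t)
    sd = x.std(axis=1)
    # relative tolerance: a numerically-constant series has sd ~ eps*|mean|
    tol = 1e-10 * (np.abs(x).max(axis=1) + 1e-300)
    degenerate = sd <= tol
    invalid = np.nonzero(degenerate)[0]
    xs = x - x.mean(axis=1, keepdims=True)
    safe_sd = np.where(degenerate, 1.0, sd)
    xs /= (safe_sd * np.sqrt(t))[:, None]
    xs[invalid] = 0.0
    values = np.clip(xs @ xs[nodes].T, -1.0, 1.0)
    return CorrelationProfile(
        values=values,
        voxel_index=mask.voxel_index,
        node_index=mask.voxel_index[nodes],
        invalid_voxels=invalid,
    )


def average_profiles(per_subject: list, groups: list) -> CorrelationProfile:
    """Two-stage mean: within each group, then across the two group means."""
    if len(per_subject) != len(groups):
        raise ValueError("profiles and group labels differ in length")
    shapes = {p.values.shape for p in per_subject}
    if len(shapes) != 1:
        raise ValueError("profiles have mismatched shapes")
    unique_groups = sorted(set(groups))
    if len(unique_groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {unique_groups}")
    means = []
    for grp in unique_groups:
        members = [p.values for p, g in zip(per_subject, groups) if g == grp]
        if not members:
            raise ValueError(f"group {grp!r} is empty")
        means.append(np.mean(members, axis=0))
    invalid = np.unique(np.concatenate([p.invalid_voxels for p in per_subject]))
    ref = per_subject[0]
    return CorrelationProfile(
        values=(means[0] + means[1]) / 2.0,
        voxel_index=ref.voxel_index,
        node_index=ref.node_index,
        invalid_voxels=invalid.astype(int),
    )


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-norm rows: ||a-b||^2 = 2 (1 - corr(a, b))."""
    x = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("constant profile row: exclude zero-variance voxels first")
    return x / norms


def _canonical_labels(raw: np.ndarray, k: int) -> np.ndarray:
    """Relabel 1..k by descending cluster size; ties by smallest member."""
    order = []
    for lab in range(k):
        members = np.nonzero(raw == lab)[0]
        order.append((-len(members), members.min() if len(members) else np.inf, lab))
    mapping = {old: new + 1 for new, (_, _, old) in enumerate(sorted(order))}
    return np.array([mapping[v] for v in raw], dtype=np.int32)


def kmeans_correlation(
    values: np.ndarray,
    k: int,
    n_replicates: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Correlation-distance k-means labels (1..k), best of ``n_replicates``.

    Rows are standardised so the Euclidean objective equals (an affine
    function of) the summed within-cluster correlation distance; labels are
    relabelled canonically (descending size, ties by smallest member).
    """
    values = np.asarray(values, dtype=np.float64)
    v = values.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if v <= k:
        raise ValueError(f"need more rows ({v}) than clusters ({k})")
    x = _standardize_rows(values)
    km = KMeans(n_clusters=k, n_init=n_replicates, random_state=seed % (2**32 - 1))
    raw = km.fit_predict(x)
    return _canonical_labels(raw, k)


def dice_coassignment(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Dice coefficient of two partitions' co-assignment (adjacency) relations.

    2 * |pairs co-clustered in both| / (|pairs in A| + |pairs in B|),
    computed by pair counting on the label contingency table — the V x V
    adjacency matrices are never materialised.  Invariant to label
    permutations; 1.0 for identical partitions.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors differ in length")

    def pair_count(counts: np.ndarray) -> float:
        return float((counts * (counts - 1)).sum() / 2.0)

    _, ia = np.unique(labels_a, return_inverse=True)
    _, ib = np.unique(labels_b, return_inverse=True)
    joint = np.bincount(ia * (ib.max() + 1) + ib)
    both = pair_count(joint)
    pa = pair_count(np.bincount(ia))
    pb = pair_count(np.bincount(ib))
    if pa + pb == 0:
        return 1.0  # two all-singleton partitions agree trivially
    return 2.0 * both / (pa + pb)


def stability_analysis(
    profile: CorrelationProfile,
    k_range=range(2, 23),
    n_folds: int = 4,
    n_replicates: int = 10,
    seed: int = 0,
) -> StabilityCurve:
    """Fold-stability curve over candidate cluster counts.

    Node columns are randomly partitioned (seeded) into ``n_folds``
    near-equal folds; each fold is clustered independently at every K and
    the voxel co-assignment Dice is averaged over all fold pairs.
    """
    values = profile.values
    if len(profile.invalid_voxels):
        keep = np.setdiff1d(np.arange(values.shape[0]), profile.invalid_voxels)
        values = values[keep]
    n = values.shape[1]
    if n < n_folds * 2:
        raise ValueError("too few node columns for the requested folds")
    root = np.random.SeedSequence(seed)
    ss_fold, ss_km = root.spawn(2)
    perm = np.random.default_rng(ss_fold).permutation(n)
    folds = np.array_split(perm, n_folds)

    k_values = np.array(sorted(k_range), dtype=int)
    km_seeds = {
        (int(k), f): _derive_seed(ss_km, int(k), f)
        for k in k_values
        for f in range(n_folds)
    }
    mean_dice = np.empty(len(k_values))
    per_pair = []
    for ki, k in enumerate(k_values):
        fold_labels = [
            kmeans_correlation(values[:, cols], int(k), n_replicates, km_seeds[(int(k), f)])
            for f, cols in enumerate(folds)
        ]
        pair_dice = [
            dice_coassignment(fold_labels[a], fold_labels[b])
            for a, b in itertools.combinations(range(n_folds), 2)
        ]
        per_pair.append(pair_dice)
        mean_dice[ki] = float(np.mean(pair_dice))
    return StabilityCurve(k_values=k_values, mean_dice=mean_dice, per_pair_dice=per_pair)


def _derive_seed(ss: np.random.SeedSequence, *key: int) -> int:
    child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=tuple(key))
    return int(child.generate_state(1)[0] % (2**31))


def select_k(curve: StabilityCurve, threshold: float = 0.85):
    """Largest K whose mean fold Dice strictly exceeds ``threshold``.

    Returns ``None`` when no candidate is stable (an explicit "no stable K"
    outcome, never a silent fallback).
    """
    if len(curve.k_values) == 0:
        raise ValueError("empty stability curve")
    stable = curve.k_values[curve.mean_dice > threshold]
    return int(stable.max()) if len(stable) else None


def assign_layers(
    parcellation: Parcellation,
    gm_mask: np.ndarray,
    voxel_size_mm: float,
    layer_map: dict | None = None,
) -> Parcellation:
    """Tag each network superficial / middle / deep by gray-matter distance.

    The per-network mean Euclidean distance (mm) to the nearest gray-matter
    voxel ranks the networks; ranks are cut into three near-equal groups
    (ceil(K/3) / ceil(K/3) / rest), lowest distances superficial.  Networks
    tied at a boundary distance share the lower (more superficial) layer.
    An explicit ``layer_map`` (network id -> layer name) overrides the
    tertile rule when a study-specific split is required.
    """
    gm_mask = np.asarray(gm_mask, dtype=bool)
    if not gm_mask.any():
        raise ValueError("empty gray-matter mask")
    dist = ndimage.distance_transform_edt(~gm_mask) * voxel_size_mm
    vi = parcellation.voxel_index
    voxel_dist = dist[vi[:, 0], vi[:, 1], vi[:, 2]]
    # label 0 (voxels excluded from clustering) carries no layer
    ids = sorted(i for i in np.unique(parcellation.labels).tolist() if i > 0)
    mean_d = {i: float(voxel_dist[parcellation.labels == i].mean()) for i in ids}
    parcellation.mean_gm_distance = mean_d

    if layer_map is not None:
        unknown = set(layer_map.values()) - set(LAYERS)
        if unknown:
            raise ValueError(f"unknown layer names {unknown}")
        parcellation.layer = {i: layer_map[i] for i in ids}
        return parcellation

    ranked = sorted(ids, key=lambda i: mean_d[i])
    k = len(ids)
    cut = int(np.ceil(k / 3))
    sup_max = mean_d[ranked[min(cut, k) - 1]]
    mid_max = mean_d[ranked[min(2 * cut, k) - 1]]
    layer = {}
    for i in ids:
        if mean_d[i] <= sup_max:
            layer[i] = "superficial"
        elif mean_d[i] <= mid_max:
            layer[i] = "middle"
        else:
            layer[i] = "deep"
    parcellation.layer = layer
    return parcellation
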