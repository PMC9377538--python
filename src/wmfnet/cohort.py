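"""Synthetic resting-state fMRI cohort with planted white-matter networks.

The generator emulates a two-group study (a patient-like group of 16 and a
control-like group of 18, 210 volumes at TR = 2 s) on a small 3-D grid with
a realistic tissue geometry: a CSF ventricle at the centre, a deep
white-matter core, a shell of superficial white-matter, a gray-matter
cortex, and outer CSF.

White matter is partitioned into ``k_true`` contiguous networks: one large
deep core plus region-grown parcels on the superficial shell.  Every voxel
in a network carries that network's band-limited latent signal; latent
signals are correlated across networks according to a group-specific
correlation matrix, and group 1 receives an additional Fisher-z offset on a
configurable set of network pairs (the planted group effect).  Gray-matter
parcels carry their own latents, correlated with the latents of
superficial white-matter networks so that white/gray-matter network
correspondence is testable.

Two features make the cohort behave like real data under stability
analysis rather than like an idealised mixture of point clusters:

* voxels also receive a small *heterogeneity* component — a mixture of
  smooth spatial random fields with their own band-limited time courses —
  so profiles vary continuously within a network;
* the deep core is given a larger heterogeneity weight (deep white matter
  has lower BOLD coherence than superficial tracts), so clusterings with
  more clusters than were planted split the core along data-dependent
  directions and are unstable across node folds.

All randomness flows from ``CohortSpec.seed`` through a seed tree; the same
seed reproduces the cohort bit for bit.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CohortSpec",
    "SubjectRecord",
    "GroundTruth",
    "ClinicalProfile",
    "CLINICAL_NORMS",
    "generate_cohort",
    "generate_motion",
    "generate_clinical",
    "latent_correlations",
    "simulate_fc_cohort",
]

GROUP1 = "dm1"
GROUP2 = "hc"

#: Generating means/SDs for clinical covariates, per group.
CLINICAL_NORMS = {
    GROUP1: {
        "age": (48.0, 14.14),
        "education": (13.0, 3.16),
        "mmse": (27.06, 1.84),
        "hamd": (6.00, 4.23),
        "duration": (6.19, 4.82),
        "p_male": 10 / 16,
    },
    GROUP2: {
        "age": (41.0, 10.65),
        "education": (14.55, 2.52),
        "mmse": (29.17, 0.92),
        "hamd": (2.06, 0.80),
        "duration": None,
        "p_male": 9 / 18,
    },
}

# Instrument / plausibility ranges used to truncate clinical draws.
_RANGES = {
    "age": (20.0, 80.0),
    "education": (0.0, 25.0),
    "mmse": (0.0, 30.0),
    "hamd": (0.0, 52.0),
    "duration": (0.0, np.inf),
}

# Random-walk step SDs at motion_scale = 1 (mm per frame, rad per frame).
_TRANS_STEP = 0.02
_ROT_STEP = 0.00015
# Patient-like group moves more, mirroring the mean-FD ratio of the
# emulated study design (0.11 vs 0.08); the lognormal sigma gives mean FD a
# within-group coefficient of variation near the reported ~0.36, so motion
# overlaps between groups instead of separating them deterministically.
_GROUP1_MOTION_FACTOR = 1.375
_MOTION_SCALE_SIGMA = 0.35

# Normalised ellipsoid radii of the tissue shells.
_RHO_VENTRICLE = 0.18
_RHO_DEEP = 0.66
_RHO_WM = 0.85
_RHO_GM = 1.0
_RHO_CSF_OUTER = 1.10

_N_FIELDS = 16
_LATENT_BAND = (0.01, 0.1)  # Hz


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort."""

    n_group1: int = 16
    n_group2: int = 18
    grid_dims: tuple = (24, 24, 18)
    voxel_size_mm: float = 3.0
    n_volumes: int = 210
    tr_s: float = 2.0
    k_true: int = 13
    effect_edges: tuple = ((0, 1), (1, 6), (3, 7), (6, 8), (7, 12))
    effect_z: float = 0.3
    noise_sd: float = 0.2
    heterogeneity_sd: float = 0.45
    deep_heterogeneity_sd: float = 0.8
    motion_scale: float = 1.0
    n_gm_networks: int = 8
    seed: int = 0

    def validate(self) -> None:
        if self.n_group1 < 1 or self.n_group2 < 1:
            raise ValueError("both groups must be non-empty")
        if len(self.grid_dims) != 3 or any(d < 4 for d in self.grid_dims):
            raise ValueError("grid_dims must be three integers >= 4")
        if self.n_volumes < 20:
            raise ValueError("n_volumes must be >= 20")
        if self.tr_s <= 0 or self.voxel_size_mm <= 0:
            raise ValueError("tr_s and voxel_size_mm must be positive")
        if self.k_true < 2:
            raise ValueError("k_true must be >= 2")
        if self.noise_sd < 0 or self.motion_scale < 0:
            raise ValueError("noise_sd and motion_scale must be non-negative")
        for i, j in self.effect_edges:
            if not (0 <= i < self.k_true and 0 <= j < self.k_true) or i == j:
                raise ValueError(f"effect edge ({i},{j}) invalid for k_true={self.k_true}")


@dataclass
class ClinicalProfile:
    age: float
    sex: str
    education: float
    mmse: float
    hamd: float
    duration: float  # NaN for the control-like group


@dataclass
class SubjectRecord:
    """One participant: image data, motion trace, group and covariates."""

    subject_id: str
    group: str
    bold: np.ndarray  # (x, y, z, t) float32
    tissue_probs: tuple  # (wm, gm, csf) float32 volumes
    motion: np.ndarray  # (t, 6)
    age: float
    sex: str
    education: float
    mmse: float
    hamd: float
    duration: float
    latents: np.ndarray | None = None  # (t, k+g) generating latent signals


@dataclass
class GroundTruth:
    """Planted structure underlying a generated cohort."""

    wm_parcel_labels: np.ndarray  # 0 = non-network; deep core = k_true
    gm_parcel_labels: np.ndarray
    group_cov_1: np.ndarray  # k x k latent correlation, group 1
    group_cov_2: np.ndarray
    joint_cov_1: np.ndarray  # (k+g) x (k+g), incl. gray-matter latents
    joint_cov_2: np.ndarray
    tissue_probs: tuple  # noiseless base (wm, gm, csf)


# ---------------------------------------------------------------------------
# building blocks


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _bandlimited_noise(
    rng: np.random.Generator, t: int, tr_s: float, n: int,
    band: tuple = _LATENT_BAND,
) -> np.ndarray:
    """(t, n) independent band-limited unit-SD signals."""
    w = rng.standard_normal((t, n))
    freqs = np.fft.rfftfreq(t, d=tr_s)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():  # degenerate short series: keep lowest non-DC bin
        keep = np.zeros_like(keep)
        keep[1] = True
    spec = np.fft.rfft(w, axis=0)
    spec[~keep] = 0
    x = np.fft.irfft(spec, n=t, axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


def _nearest_correlation(c: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD matrix w/ unit diagonal."""
    c = (c + c.T) / 2.0
    vals, vecs = np.linalg.eigh(c)
    vals = np.clip(vals, 1e-8, None)
    c = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c


def latent_correlations(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Joint latent correlation matrices for the two groups.

    Returns ``(joint_1, joint_2, wm_1, wm_2)`` where the joint matrices are
    (k+g) x (k+g) over white- then gray-matter latents and the wm matrices
    are their leading k x k blocks.  Group 1 equals group 2 with
    ``effect_z`` added on ``effect_edges`` in the Fisher-z domain and the
    result projected back to the nearest correlation matrix; with
    ``effect_z == 0`` the two are identical by construction.
    """
    spec.validate()
    k, g = spec.k_true, spec.n_gm_networks
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))

    c = np.full((k + g, k + g), 0.0)
    # white-matter block: weak baseline coupling with seeded jitter
    wm = np.full((k, k), 0.15) + rng.uniform(-0.05, 0.05, (k, k))
    wm = (wm + wm.T) / 2.0
    wm[k - 1, :] = wm[:, k - 1] = 0.10  # deep core couples weakly
    c[:k, :k] = wm
    # gray-matter block
    c[k:, k:] = 0.10
    # superficial WM networks share signal with a gray-matter partner
    for j in range(k - 1):
        c[j, k + (j % g)] = c[k + (j % g), j] = 0.70
    np.fill_diagonal(c, 1.0)
    joint_2 = _nearest_correlation(c)

    if spec.effect_z == 0:
        joint_1 = joint_2.copy()
    else:
        z = np.arctanh(np.clip(joint_2, -1 + 1e-7, 1 - 1e-7))
        for i, j in spec.effect_edges:
            z[i, j] += spec.effect_z
            z[j, i] += spec.effect_z
        c1 = np.tanh(z)
        np.fill_diagonal(c1, 1.0)
        joint_1 = _nearest_correlation(c1)
    return joint_1, joint_2, joint_1[:k, :k].copy(), joint_2[:k, :k].copy()


def _geometry(grid_dims: tuple) -> np.ndarray:
    """Normalised ellipsoidal radius at every voxel."""
    axes = [np.arange(n, dtype=np.float64) for n in grid_dims]
    centers = [(n - 1) / 2.0 for n in grid_dims]
    radii = [n / 2.0 - 0.7 for n in grid_dims]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(
        ((gx - centers[0]) / radii[0]) ** 2
        + ((gy - centers[1]) / radii[1]) ** 2
        + ((gz - centers[2]) / radii[2]) ** 2
    )


def _farthest_point_seeds(coords: np.ndarray, n_seeds: int, rng) -> np.ndarray:
    first = int(rng.integers(len(coords)))
    chosen = [first]
    dmin = np.linalg.norm(coords - coords[first], axis=1)
    for _ in range(n_seeds - 1):
        nxt = int(np.argmax(dmin))
        chosen.append(nxt)
        dmin = np.minimum(dmin, np.linalg.norm(coords - coords[nxt], axis=1))
    return np.array(chosen)


def _grow_parcels(coords: np.ndarray, n_parcels: int, rng) -> np.ndarray:
    """Partition a voxel set into contiguous parcels by randomised
    multi-source Dijkstra growth from farthest-point seeds (6-connectivity)."""
    index = {tuple(c): i for i, c in enumerate(coords)}
    labels = np.zeros(len(coords), dtype=np.int32)
    seeds = _farthest_point_seeds(coords, n_parcels, rng)
    heap = []
    counter = 0
    for lab, s in enumerate(seeds, start=1):
        heapq.heappush(heap, (0.0, counter, int(s), lab))
        counter += 1
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while heap:
        dist, _, vi, lab = heapq.heappop(heap)
        if labels[vi]:
            continue
        labels[vi] = lab
        cx, cy, cz = coords[vi]
        for ox, oy, oz in offsets:
            nb = index.get((cx + ox, cy + oy, cz + oz))
            if nb is not None and not labels[nb]:
                heapq.heappush(heap, (dist + rng.uniform(0.5, 1.5), counter, nb, lab))
                counter += 1
    # voxels unreachable from any seed (isolated islands): attach to the
    # nearest seed's parcel by Euclidean distance
    for vi in np.nonzero(labels == 0)[0]:
        d = np.linalg.norm(coords[seeds] - coords[vi], axis=1)
        labels[vi] = int(np.argmin(d)) + 1
    return labels


def _base_tissue_probs(rho: np.ndarray) -> tuple:
    wm_bin = ((rho > _RHO_VENTRICLE) & (rho <= _RHO_WM)).astype(np.float64)
    gm_bin = ((rho > _RHO_WM) & (rho <= _RHO_GM)).astype(np.float64)
    csf_bin = ((rho <= _RHO_VENTRICLE) | ((rho > _RHO_GM) & (rho <= _RHO_CSF_OUTER))).astype(np.float64)
    brain = (wm_bin + gm_bin + csf_bin) > 0
    wm = ndimage.gaussian_filter(wm_bin, 0.7)
    gm = ndimage.gaussian_filter(gm_bin, 0.7)
    csf = ndimage.gaussian_filter(csf_bin, 0.7)
    total = wm + gm + csf
    total[total == 0] = 1.0
    scale = np.where(brain, total, 1.0)
    wm, gm, csf = wm / scale, gm / scale, csf / scale
    for vol in (wm, gm, csf):
        vol[~brain] = 0.0
    return wm.astype(np.float32), gm.astype(np.float32), csf.astype(np.float32)


def _plant_parcels(spec: CohortSpec, rho: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth WM and GM parcel label volumes."""
    k, g = spec.k_true, spec.n_gm_networks
    wm_labels = np.zeros(spec.grid_dims, dtype=np.int32)
    gm_labels = np.zeros(spec.grid_dims, dtype=np.int32)

    deep = (rho > _RHO_VENTRICLE) & (rho <= _RHO_DEEP)
    shell = (rho > _RHO_DEEP) & (rho <= _RHO_WM)
    gm_zone = (rho > _RHO_WM) & (rho <= _RHO_GM)

    n_shell_parcels = k - 1
    shell_coords = np.argwhere(shell)
    if len(shell_coords) < n_shell_parcels * 4:
        raise ValueError(
            f"cannot place {n_shell_parcels} shell parcels on "
            f"{len(shell_coords)} shell voxels; enlarge grid_dims"
        )
    wm_labels[deep] = k  # deep core is the last network
    shell_lab = _grow_parcels(shell_coords, n_shell_parcels, rng)
    wm_labels[shell_coords[:, 0], shell_coords[:, 1], shell_coords[:, 2]] = shell_lab

    gm_coords = np.argwhere(gm_zone)
    if len(gm_coords) < g * 4:
        raise ValueError("cannot place gray-matter parcels; enlarge grid_dims")
    gm_lab = _grow_parcels(gm_coords, g, rng)
    gm_labels[gm_coords[:, 0], gm_coords[:, 1], gm_coords[:, 2]] = gm_lab
    return wm_labels, gm_labels


def _spatial_fields(
    grid_dims: tuple, rng, wm_labels: np.ndarray, n_fields: int = _N_FIELDS
) -> np.ndarray:
    """Smooth unit-norm per-voxel field-loading vectors, shape (*grid, M).

    Within every white-matter network the loadings are whitened (over that
    network's own voxels) so each network's heterogeneity cloud is
    isotropic in field space: no direction of within-network variation
    dominates, and a clustering forced to subdivide a network has no
    preferred seam — subdivisions are decided by node-sampling noise and
    are therefore unstable across folds, as in real data.
    """
    fields = np.stack(
        [ndimage.gaussian_filter(rng.standard_normal(grid_dims), 2.0) for _ in range(n_fields)],
        axis=-1,
    )
    for net in np.unique(wm_labels):
        if net == 0:
            continue
        sel = wm_labels == net
        if sel.sum() <= n_fields:
            continue
        cov = np.cov(fields[sel].T)
        vals, vecs = np.linalg.eigh(cov)
        whiten = (vecs / np.sqrt(np.clip(vals, 1e-12, None))) @ vecs.T
        fields[sel] = fields[sel] @ whiten
    norm = np.linalg.norm(fields, axis=-1, keepdims=True)
    norm[norm == 0] = 1.0
    return fields / norm


# ---------------------------------------------------------------------------
# public operations


def generate_motion(
    spec: CohortSpec,
    t: int,
    seed: int,
    spikes: Sequence[tuple] = (),
) -> np.ndarray:
    """Random-walk rigid-motion trace (t x 6), scaled by ``motion_scale``.

    ``spikes`` is a sequence of ``(frame, magnitude_mm)`` pairs; each adds a
    sustained displacement starting at ``frame`` so that framewise
    displacement shows a single spike there (useful for scrubbing tests).
    """
    if t < 2:
        raise ValueError("need t >= 2")
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((t, 6))
    steps[:, :3] *= _TRANS_STEP * spec.motion_scale
    steps[:, 3:] *= _ROT_STEP * spec.motion_scale
    steps[0] = 0.0
    trace = np.cumsum(steps, axis=0)
    for frame, magnitude in spikes:
        if not (0 < frame < t):
            raise ValueError(f"spike frame {frame} outside 1..{t - 1}")
        trace[frame:, 0] += magnitude
    return trace


def generate_clinical(spec: CohortSpec, group: str, seed: int) -> ClinicalProfile:
    """Draw one subject's covariates/clinical scores for ``group``.

    Scores are normal draws with the group generating means/SDs, truncated
    to instrument ranges (e.g. MMSE clipped to [0, 30]).
    """
    if group not in CLINICAL_NORMS:
        raise ValueError(f"unknown group {group!r}")
    norms = CLINICAL_NORMS[group]
    rng = np.random.default_rng(seed)
    values = {}
    for name in ("age", "education", "mmse", "hamd", "duration"):
        spec_ms = norms[name]
        if spec_ms is None:
            values[name] = float("nan")
            continue
        mean, sd = spec_ms
        lo, hi = _RANGES[name]
        values[name] = float(np.clip(rng.normal(mean, sd), lo, hi))
    sex = "M" if rng.random() < norms["p_male"] else "F"
    return ClinicalProfile(
        age=values["age"],
        sex=sex,
        education=values["education"],
        mmse=values["mmse"],
        hamd=values["hamd"],
        duration=values["duration"],
    )


def generate_cohort(spec: CohortSpec) -> tuple[list, GroundTruth]:
    """Generate the full cohort and its ground truth."""
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    ss_parcel, ss_field, ss_tissue, ss_subjects = root.spawn(4)

    rho = _geometry(spec.grid_dims)
    wm_labels, gm_labels = _plant_parcels(
        spec, rho, np.random.default_rng(ss_parcel)
    )
    base_probs = _base_tissue_probs(rho)
    fields = _spatial_fields(
        spec.grid_dims, np.random.default_rng(ss_field), wm_labels
    )

    joint_1, joint_2, wm_1, wm_2 = latent_correlations(spec)
    chol = {GROUP1: np.linalg.cholesky(joint_1), GROUP2: np.linalg.cholesky(joint_2)}

    k, g = spec.k_true, spec.n_gm_networks
    t = spec.n_volumes
    csf_zone = base_probs[2] > 0.5

    tissue_rng = np.random.default_rng(ss_tissue)
    groups = [GROUP1] * spec.n_group1 + [GROUP2] * spec.n_group2
    subjects = []
    for idx, group in enumerate(groups):
        ss = ss_subjects.spawn(1)[0]
        ss_sig, ss_noise, ss_mot, ss_clin = ss.spawn(4)
        rng_sig = np.random.default_rng(ss_sig)
        rng_noise = np.random.default_rng(ss_noise)

        white = _bandlimited_noise(rng_sig, t, spec.tr_s, k + g)
        latents = white @ chol[group].T
        h_fields = _bandlimited_noise(rng_sig, t, spec.tr_s, _N_FIELDS)
        csf_sig = _bandlimited_noise(rng_sig, t, spec.tr_s, 1)[:, 0]

        bold = np.zeros(spec.grid_dims + (t,), dtype=np.float32)
        for net in range(1, k + 1):
            sel = wm_labels == net
            n_vox = int(sel.sum())
            series = np.broadcast_to(latents[:, net - 1], (n_vox, t)).copy()
            het = spec.deep_heterogeneity_sd if net == k else spec.heterogeneity_sd
            if het > 0:
                series += het * (fields[sel] @ h_fields.T)
            if spec.noise_sd > 0:
                series += spec.noise_sd * rng_noise.standard_normal((n_vox, t))
            bold[sel] = series.astype(np.float32)
        for net in range(1, g + 1):
            sel = gm_labels == net
            n_vox = int(sel.sum())
            series = np.broadcast_to(latents[:, k + net - 1], (n_vox, t)).copy()
            if spec.heterogeneity_sd > 0:
                series += spec.heterogeneity_sd * (fields[sel] @ h_fields.T)
            if spec.noise_sd > 0:
                series += spec.noise_sd * rng_noise.standard_normal((n_vox, t))
            bold[sel] = series.astype(np.float32)
        n_csf = int(csf_zone.sum())
        csf_series = 0.7 * np.broadcast_to(csf_sig, (n_csf, t)).copy()
        if spec.noise_sd > 0:
            csf_series = csf_series + spec.noise_sd * rng_noise.standard_normal((n_csf, t))
        bold[csf_zone] = csf_series.astype(np.float32)

        probs = []
        for base in base_probs:
            jitter = tissue_rng.normal(0.0, 0.04, size=base.shape).astype(np.float32)
            p = np.clip(base + np.where(base > 0, jitter, 0.0), 0.0, 1.0)
            probs.append(p)
        total = probs[0] + probs[1] + probs[2]
        scale = np.where(total > 1.0, total, 1.0)
        probs = tuple((p / scale).astype(np.float32) for p in probs)

        mscale = _GROUP1_MOTION_FACTOR if group == GROUP1 else 1.0
        mscale *= float(np.random.default_rng(ss_mot).lognormal(0.0, _MOTION_SCALE_SIGMA))
        motion_spec = replace(spec, motion_scale=spec.motion_scale * mscale)
        motion = generate_motion(motion_spec, t, _child_seed(ss_mot))
        clin = generate_clinical(spec, group, _child_seed(ss_clin))

        subjects.append(
            SubjectRecord(
                subject_id=f"sub-{idx + 1:02d}",
                group=group,
                bold=bold,
                tissue_probs=probs,
                motion=motion,
                age=clin.age,
                sex=clin.sex,
                education=clin.education,
                mmse=clin.mmse,
                hamd=clin.hamd,
                duration=clin.duration,
                latents=latents,
            )
        )

    truth = GroundTruth(
        wm_parcel_labels=wm_labels,
        gm_parcel_labels=gm_labels,
        group_cov_1=wm_1,
        group_cov_2=wm_2,
        joint_cov_1=joint_1,
        joint_cov_2=joint_2,
        tissue_probs=base_probs,
    )
    return subjects, truth


def simulate_fc_cohort(
    cov1: np.ndarray,
    cov2: np.ndarray,
    n_group1: int = 16,
    n_group2: int = 18,
    n_samples: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, list, pd.DataFrame]:
    """Matrix-level cohort: per-subject Fisher-z FC sampled directly.

    Each subject's K-network time courses are ``n_samples`` multivariate
    normal draws with the group's latent correlation; the empirical Pearson
    matrix is Fisher-z transformed.  Covariates (age, education, sex, mean
    FD) are drawn independently of group membership, so with
    ``cov1 is cov2`` the cohort is an exact group null.  Used for
    permutation-calibration studies where full image simulation adds
    nothing.
    """
    cov1 = np.asarray(cov1, dtype=np.float64)
    cov2 = np.asarray(cov2, dtype=np.float64)
    if cov1.shape != cov2.shape or cov1.shape[0] != cov1.shape[1]:
        raise ValueError("cov1/cov2 must be square and same shape")
    k = cov1.shape[0]
    rng = np.random.default_rng(seed)
    chol = {GROUP1: np.linalg.cholesky(cov1), GROUP2: np.linalg.cholesky(cov2)}
    groups = [GROUP1] * n_group1 + [GROUP2] * n_group2
    z = np.empty((len(groups), k, k))
    rows = []
    for i, grp in enumerate(groups):
        x = rng.standard_normal((n_samples, k)) @ chol[grp].T
        r = np.corrcoef(x.T)
        r = np.clip(r, -1 + 1e-7, 1 - 1e-7)
        zi = np.arctanh(r)
        np.fill_diagonal(zi, np.nan)
        z[i] = zi
        rows.append(
            {
                "subject_id": f"sub-{i + 1:02d}",
                "group": grp,
                "age": float(np.clip(rng.normal(44.3, 12.5), 20, 80)),
                "education": float(np.clip(rng.normal(13.8, 2.9), 0, 25)),
                "sex": "M" if rng.random() < 0.56 else "F",
                "mean_fd": float(np.clip(rng.normal(0.095, 0.035), 0.01, None)),
            }
        )
    return z, groups, pd.DataFrame(rows)
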