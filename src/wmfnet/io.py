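"""On-disk formats: NIfTI volumes, TSV tables, JSON reports.

A cohort directory holds ``participants.tsv``, per-subject
``<id>_bold.nii.gz``, ``<id>_tissue-{wm,gm,csf}.nii.gz`` and
``<id>_motion.tsv``, plus optional ground-truth label volumes
(``truth_wm_labels.nii.gz`` / ``truth_gm_labels.nii.gz``) and latent
covariance TSVs when the cohort was simulated.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import CohortSpec, GroundTruth, SubjectRecord
from .mask import GroupMask

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
PARTICIPANT_COLUMNS = [
    "subject_id", "group", "age", "sex", "education", "mmse", "hamd", "duration",
]


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def save_nifti(data: np.ndarray, path, voxel_size_mm: float = 3.0, dtype=None) -> None:
    if dtype is not None:
        data = np.asarray(data, dtype=dtype)
    nib.save(nib.Nifti1Image(data, _affine(voxel_size_mm)), str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def write_cohort(
    subjects: list, truth: GroundTruth | None, spec: CohortSpec, out_dir
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vox = spec.voxel_size_mm
    rows = []
    for s in subjects:
        save_nifti(s.bold, out / f"{s.subject_id}_bold.nii.gz", vox, np.float32)
        for name, vol in zip(("wm", "gm", "csf"), s.tissue_probs):
            save_nifti(vol, out / f"{s.subject_id}_tissue-{name}.nii.gz", vox, np.float32)
        pd.DataFrame(s.motion, columns=MOTION_COLUMNS).to_csv(
            out / f"{s.subject_id}_motion.tsv", sep="\t", index=False, float_format="%.8g"
        )
        rows.append({c: getattr(s, c) for c in PARTICIPANT_COLUMNS})
    pd.DataFrame(rows).to_csv(out / "participants.tsv", sep="\t", index=False, float_format="%.6g")
    with open(out / "cohort_spec.json", "w") as fh:
        json.dump(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in spec.__dict__.items()},
            fh, indent=2,
        )
    if truth is not None:
        save_nifti(truth.wm_parcel_labels, out / "truth_wm_labels.nii.gz", vox, np.int16)
        save_nifti(truth.gm_parcel_labels, out / "truth_gm_labels.nii.gz", vox, np.int16)
        np.savetxt(out / "truth_group_cov_1.tsv", truth.group_cov_1, delimiter="\t")
        np.savetxt(out / "truth_group_cov_2.tsv", truth.group_cov_2, delimiter="\t")


def load_cohort(cohort_dir) -> tuple[list, dict]:
    """Subjects plus a dict of optional ground-truth volumes."""
    root = Path(cohort_dir)
    table = pd.read_csv(root / "participants.tsv", sep="\t")
    subjects = []
    for _, row in table.iterrows():
        sid = row["subject_id"]
        bold = np.asarray(load_nifti(root / f"{sid}_bold.nii.gz"), dtype=np.float32)
        probs = tuple(
            np.asarray(load_nifti(root / f"{sid}_tissue-{n}.nii.gz"), dtype=np.float32)
            for n in ("wm", "gm", "csf")
        )
        motion = pd.read_csv(root / f"{sid}_motion.tsv", sep="\t")[MOTION_COLUMNS].to_numpy()
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=row["group"],
                bold=bold,
                tissue_probs=probs,
                motion=motion,
                age=float(row["age"]),
                sex=row["sex"],
                education=float(row["education"]),
                mmse=float(row["mmse"]),
                hamd=float(row["hamd"]),
                duration=float(row["duration"]),
            )
        )
    truth = {}
    for key, fname in (
        ("wm_labels", "truth_wm_labels.nii.gz"),
        ("gm_labels", "truth_gm_labels.nii.gz"),
    ):
        if (root / fname).exists():
            truth[key] = np.asarray(load_nifti(root / fname))
    return subjects, truth


def write_group_mask(mask: GroupMask, out_dir, voxel_size_mm: float, prefix: str) -> None:
    out = Path(out_dir)
    save_nifti(mask.mask.astype(np.uint8), out / f"{prefix}_mask.nii.gz", voxel_size_mm)
    save_nifti(mask.fraction_map, out / f"{prefix}_fraction.nii.gz", voxel_size_mm, np.float32)


def write_parcellation(parc, shape, out_dir, voxel_size_mm: float, prefix="parcellation") -> None:
    out = Path(out_dir)
    save_nifti(parc.label_volume(shape), out / f"{prefix}.nii.gz", voxel_size_mm, np.int16)
    sizes = parc.network_sizes()
    pd.DataFrame(
        {
            "network_id": sorted(sizes),
            "n_voxels": [sizes[i] for i in sorted(sizes)],
            "layer": [parc.layer.get(i, "") for i in sorted(sizes)],
            "mean_gm_distance_mm": [parc.mean_gm_distance.get(i, np.nan) for i in sorted(sizes)],
        }
    ).to_csv(out / f"{prefix}.tsv", sep="\t", index=False, float_format="%.4f")


def write_stability(curve, path) -> None:
    n_pairs = len(curve.per_pair_dice[0]) if curve.per_pair_dice else 0
    frame = pd.DataFrame(
        {
            "k": curve.k_values,
            "mean_dice": curve.mean_dice,
            **{
                f"pair{j}_dice": [pairs[j] for pairs in curve.per_pair_dice]
                for j in range(n_pairs)
            },
        }
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_fc_matrix(fcm, path) -> None:
    iu, ju = np.triu_indices(fcm.k, 1)
    pd.DataFrame(
        {
            "net_i": fcm.network_ids[iu],
            "net_j": fcm.network_ids[ju],
            "r": fcm.r[iu, ju],
            "z": fcm.z[iu, ju],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_edge_stats(stats, path) -> None:
    frame = pd.DataFrame(
        {
            "net_i": stats.edges[:, 0] + 1,
            "net_j": stats.edges[:, 1] + 1,
            "t": stats.t,
            "p_uncorr": stats.p if stats.p is not None else np.nan,
        }
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_nbs(result, path, seed: int | None = None) -> None:
    payload = {
        "components": [
            {
                "edges": [[i + 1, j + 1] for i, j in comp],
                "size": size,
                "sign": sign,
                "corrected_p": p,
                "significant": p < result.alpha,
            }
            for comp, size, sign, p in zip(
                result.components, result.component_size,
                result.component_sign, result.corrected_p,
            )
        ],
        "primary_threshold_p": result.primary_threshold,
        "alpha": result.alpha,
        "n_permutations": result.n_permutations,
        "direction": result.direction,
        "seed": seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
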