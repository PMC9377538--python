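"""End-to-end pipeline driver.

Stage order is fixed and logged: volume dropping and motion QC, nuisance
regression with spike regressors, band-pass filtering, group tissue masks,
within-mask smoothing, node subsampling and correlation profiles,
stability-selected k-means parcellation with layer assignment, network FC,
permutation/NBS group comparison, and clinical association on the altered
edges.  Every stage writes inspectable TSV/NIfTI/JSON artifacts named
after the configuration hash, plus a provenance log.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, clinical, clustering, fc, inference, io, preprocess
from .cohort import GROUP1
from .config import PipelineConfig
from .mask import GroupMask, group_mask, subject_tissue_label, apply_exclusion

log = logging.getLogger("wmfnet")

STAGES = ("preprocess", "mask", "cluster", "fc", "compare", "correlate")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _seed_for(config: PipelineConfig, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def _gm_network_timecourses(bold: np.ndarray, gm_labels: np.ndarray) -> fc.NetworkTimeCourses:
    ids = np.array(sorted(int(i) for i in np.unique(gm_labels) if i > 0))
    series = np.stack([bold[gm_labels == i].mean(axis=0) for i in ids])
    return fc.NetworkTimeCourses(series=np.asarray(series, dtype=np.float64), network_ids=ids)


def run_pipeline(
    config: PipelineConfig,
    cohort_dir,
    out_dir,
    until: str = "correlate",
    exclusion_path=None,
) -> dict:
    """Run the pipeline on a cohort directory up to stage ``until``.

    Returns a result bundle of in-memory objects; artifacts are written to
    ``out_dir``.  Any stage failure raises :class:`StageError` naming the
    stage (and subject, where applicable).
    """
    config.validate()
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}")
    last = STAGES.index(until)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = config.config_hash()

    subjects, truth = io.load_cohort(cohort_dir)
    spec_path = Path(cohort_dir) / "cohort_spec.json"
    voxel_size = 3.0
    tr_s = 2.0
    if spec_path.exists():
        with open(spec_path) as fh:
            meta = json.load(fh)
        voxel_size = float(meta.get("voxel_size_mm", voxel_size))
        tr_s = float(meta.get("tr_s", tr_s))

    results: dict = {"config_hash": tag}
    counts: dict = {"n_subjects": len(subjects)}

    # ---- preprocess -------------------------------------------------------
    qc_rows = []
    included, summaries, labels = [], [], []
    for s in subjects:
        try:
            excluded = preprocess.max_motion_exceeded(
                s.motion, config.max_translation_mm, config.max_rotation_deg
            )
            bold = preprocess.drop_initial_volumes(s.bold, config.n_drop)
            motion = s.motion[config.n_drop:]
            summary = preprocess.summarize_motion(
                motion, config.head_radius_mm, config.spike_fd_threshold
            )
            qc_rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "mean_fd": summary.mean_fd,
                    "mean_rel_rms": summary.mean_rel_rms,
                    "n_spikes": len(summary.spike_frames),
                    "included": not excluded,
                }
            )
            if excluded:
                log.warning("excluding %s: maximum head motion exceeded", s.subject_id)
                continue
            lab = subject_tissue_label(s.tissue_probs)
            csf_mask = lab == 3
            csf_signal = (
                bold[csf_mask].mean(axis=0) if csf_mask.any() else np.zeros(bold.shape[-1])
            )
            design = preprocess.build_nuisance_design(
                motion, csf_signal, summary.fd, config.spike_fd_threshold
            )
            clean = preprocess.nuisance_regress(bold, design, lab > 0)
            clean = preprocess.bandpass(clean, tr_s, config.band_low_hz, config.band_high_hz)
            s.bold = clean.astype(np.float32)
            included.append(s)
            summaries.append(summary)
            labels.append(lab)
        except Exception as err:  # noqa: BLE001 - re-raise with stage context
            raise StageError("preprocess", f"subject {s.subject_id}: {err}") from err
    pd.DataFrame(qc_rows).to_csv(out / f"qc_{tag}.tsv", sep="\t", index=False, float_format="%.6g")
    counts["n_included"] = len(included)
    counts["n_excluded"] = len(subjects) - len(included)
    results.update(subjects=included, motion_summaries=summaries, qc=pd.DataFrame(qc_rows))
    if last == 0:
        _write_provenance(config, counts, out, tag)
        return results

    # ---- group masks ------------------------------------------------------
    try:
        wm = group_mask(labels, "WM", config.wm_threshold)
        gm = group_mask(labels, "GM", config.gm_threshold)
        if exclusion_path is not None:
            wm = apply_exclusion(wm, io.load_nifti(exclusion_path) > 0)
        if wm.n_voxels == 0:
            raise ValueError("empty group white-matter mask")
    except StageError:
        raise
    except Exception as err:
        raise StageError("mask", str(err)) from err
    io.write_group_mask(wm, out, voxel_size, f"wm_{tag}")
    io.write_group_mask(gm, out, voxel_size, f"gm_{tag}")
    counts["n_wm_voxels"] = wm.n_voxels
    counts["n_gm_voxels"] = gm.n_voxels
    results.update(wm_mask=wm, gm_mask=gm)
    if last == 1:
        _write_provenance(config, counts, out, tag)
        return results

    # within-compartment smoothing needs the group masks, hence here
    for s in included:
        smoothed = preprocess.smooth_within_mask(
            s.bold, wm.mask, config.fwhm_mm, voxel_size
        )
        s.bold = np.where(wm.mask[..., None], smoothed, s.bold).astype(np.float32)

    # ---- clustering -------------------------------------------------------
    try:
        nodes = clustering.interchanging_grid_subsample(wm)
        profiles = [
            clustering.correlation_profile(s.bold, wm, nodes) for s in included
        ]
        avg = clustering.average_profiles(profiles, [s.group for s in included])
        curve = clustering.stability_analysis(
            avg,
            k_range=range(config.k_min, config.k_max + 1),
            n_folds=config.n_folds,
            n_replicates=config.n_replicates,
            seed=_seed_for(config, 1),
        )
        k = config.fixed_k or clustering.select_k(curve, config.stability_threshold)
        if k is None:
            raise ValueError(
                "no stable K: no candidate exceeded the stability threshold"
            )
        valid = np.setdiff1d(np.arange(avg.n_voxels), avg.invalid_voxels)
        labels_valid = clustering.kmeans_correlation(
            avg.values[valid], k, config.n_replicates, _seed_for(config, 2)
        )
        full_labels = np.zeros(avg.n_voxels, dtype=np.int32)
        full_labels[valid] = labels_valid
        parc = clustering.Parcellation(labels=full_labels, k=k, voxel_index=wm.voxel_index)
        parc = clustering.assign_layers(parc, gm.mask, voxel_size, config.layer_map)
    except StageError:
        raise
    except Exception as err:
        raise StageError("cluster", str(err)) from err
    io.write_stability(curve, out / f"stability_{tag}.tsv")
    io.write_parcellation(parc, wm.mask.shape, out, voxel_size, f"parcellation_{tag}")
    counts.update(n_nodes=len(nodes), selected_k=int(k))
    results.update(nodes=nodes, profiles=profiles, avg_profile=avg, curve=curve,
                   parcellation=parc, k=int(k))
    if last == 2:
        _write_provenance(config, counts, out, tag)
        return results

    # ---- network FC -------------------------------------------------------
    try:
        fcs, wm_tcs = [], []
        for s in included:
            tc = fc.network_timecourses(s.bold, parc, wm)
            wm_tcs.append(tc)
            fcs.append(fc.fc_matrix(tc))
            io.write_fc_matrix(fcs[-1], out / f"fc_{s.subject_id}_{tag}.tsv")
        correspondence = None
        if "gm_labels" in truth:
            gm_tcs = [
                _gm_network_timecourses(s.bold, truth["gm_labels"]) for s in included
            ]
            correspondence = fc.gm_correspondence_cohort(
                wm_tcs, gm_tcs, config.gm_report_threshold
            )
    except StageError:
        raise
    except Exception as err:
        raise StageError("fc", str(err)) from err
    results.update(fc_matrices=fcs, wm_timecourses=wm_tcs, correspondence=correspondence)
    if last == 3:
        _write_provenance(config, counts, out, tag)
        return results

    # ---- group comparison -------------------------------------------------
    try:
        covariates = pd.DataFrame(
            {
                "age": [s.age for s in included],
                "education": [s.education for s in included],
                "sex": [s.sex for s in included],
                "mean_fd": [m.mean_fd for m in summaries],
            }
        )
        groups = [s.group for s in included]
        stats = inference.permutation_null(
            fcs,
            groups,
            covariates,
            n_permutations=config.n_permutations,
            seed=_seed_for(config, 3),
            scheme=config.permutation_scheme,
        )
        nbs = inference.nbs_correct(
            stats, config.primary_threshold_p, config.alpha, config.direction
        )
    except StageError:
        raise
    except Exception as err:
        raise StageError("compare", str(err)) from err
    io.write_edge_stats(stats, out / f"edge_stats_{tag}.tsv")
    io.write_nbs(nbs, out / f"nbs_{tag}.json", seed=config.seed)
    _write_matrix_report(stats, out / f"group_matrix_{tag}.tsv")
    counts["n_significant_components"] = int(sum(nbs.significant))
    results.update(edge_stats=stats, nbs=nbs, covariates=covariates)
    if last == 4:
        _write_provenance(config, counts, out, tag)
        return results

    # ---- clinical association --------------------------------------------
    try:
        if config.all_edges:
            tested = [tuple(e) for e in stats.edges]
        else:
            tested = sorted(
                {e for comp, sig in zip(nbs.components, nbs.significant) if sig for e in comp}
            )
        patients = [
            (s, m) for s, m in zip(included, summaries) if s.group == GROUP1
        ]
        if tested and patients:
            z_pat = np.stack(
                [f.z for f, s in zip(fcs, included) if s.group == GROUP1]
            )
            edge_frame = pd.DataFrame(
                {f"WM{i + 1}-WM{j + 1}": z_pat[:, i, j] for i, j in tested}
            )
            scores = pd.DataFrame(
                {
                    "mmse": [s.mmse for s, _ in patients],
                    "hamd": [s.hamd for s, _ in patients],
                    "duration": [s.duration for s, _ in patients],
                }
            ).dropna(axis=1, how="all")
            covs = pd.DataFrame(
                {
                    "age": [s.age for s, _ in patients],
                    "sex": [1.0 if s.sex == "M" else 0.0 for s, _ in patients],
                    "education": [s.education for s, _ in patients],
                    "mean_fd": [m.mean_fd for _, m in patients],
                }
            )
            assoc = clinical.associate(edge_frame, scores, covs, config.fdr_q)
        else:
            assoc = pd.DataFrame(
                columns=["edge", "score", "partial_r", "p", "q", "significant"]
            )
    except StageError:
        raise
    except Exception as err:
        raise StageError("correlate", str(err)) from err
    assoc.to_csv(out / f"clinical_assoc_{tag}.tsv", sep="\t", index=False, float_format="%.6g")
    counts["n_assoc_tested"] = len(assoc)
    results["assoc"] = assoc
    _write_provenance(config, counts, out, tag)
    return results


def _write_matrix_report(stats, path) -> None:
    """Square t and p matrices (long TSV) for figure-style reporting."""
    k = stats.k
    tmat = np.full((k, k), np.nan)
    pmat = np.full((k, k), np.nan)
    for (i, j), t, p in zip(stats.edges, stats.t, stats.p):
        tmat[i, j] = tmat[j, i] = t
        pmat[i, j] = pmat[j, i] = p
    rows = []
    for i in range(k):
        for j in range(k):
            rows.append({"net_i": i + 1, "net_j": j + 1, "t": tmat[i, j], "p": pmat[i, j]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def _write_provenance(config: PipelineConfig, counts: dict, out: Path, tag: str) -> None:
    import scipy
    import sklearn

    payload = {
        "config_hash": tag,
        "config": {k: (str(v) if isinstance(v, dict) else v) for k, v in config.__dict__.items()},
        "versions": {
            "wmfnet": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "sklearn": sklearn.__version__,
            "pandas": pd.__version__,
        },
        "counts": counts,
    }
    with open(out / f"provenance_{tag}.json", "w") as fh:
        json.dump(payload, fh, indent=2)
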