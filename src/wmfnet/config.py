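"""Pipeline configuration: every tunable threshold in one serialisable place.

Defaults follow the analysis conventions this pipeline implements: drop 10
volumes, FD spike threshold 1 (50 mm rotation sphere), 2 mm / 2 degree
exclusion, 0.01–0.15 Hz band, 4 mm FWHM within-mask smoothing, 60 %
group-mask rule, K scanned over 2..22 with 4 folds and 10 k-means
replicates, 0.85 Dice stability threshold, 1,000 permutations with p < 0.05
and NBS correction, FDR q = 0.05.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # preprocessing
    n_drop: int = 10
    head_radius_mm: float = 50.0
    spike_fd_threshold: float = 1.0
    max_translation_mm: float = 2.0
    max_rotation_deg: float = 2.0
    band_low_hz: float = 0.01
    band_high_hz: float = 0.15
    fwhm_mm: float = 4.0
    # group masks
    wm_threshold: float = 0.6
    gm_threshold: float = 0.6
    # clustering / stability
    k_min: int = 2
    k_max: int = 22
    n_folds: int = 4
    n_replicates: int = 10
    stability_threshold: float = 0.85
    fixed_k: int | None = None  # bypass stability selection when set
    layer_map: dict | None = None  # optional explicit network -> layer override
    # group inference
    n_permutations: int = 1000
    primary_threshold_p: float = 0.05
    alpha: float = 0.05
    direction: str = "two-sided"
    permutation_scheme: str = "freedman_lane"
    # clinical association
    fdr_q: float = 0.05
    all_edges: bool = False  # test all edges, not only NBS-significant ones
    # correspondence reporting
    gm_report_threshold: float = 0.4
    # randomness
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def validate(self) -> None:
        if not (2 <= self.k_min <= self.k_max):
            raise ValueError("need 2 <= k_min <= k_max")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not (0 < self.stability_threshold < 1):
            raise ValueError("stability_threshold must be in (0, 1)")
        if self.band_low_hz >= self.band_high_hz:
            raise ValueError("band_low_hz must be below band_high_hz")
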