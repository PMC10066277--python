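"""Run configuration, validation, and seed-substream management.

All randomness in the package flows from a single master seed; each pipeline
stage draws from a named substream so that stages are reproducible in
isolation and insensitive to the order in which other stages run.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

DEFAULT_THRESHOLDS = (0.005, 0.001, 0.0005, 0.0001, 0.00005, 0.00001)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, collision-resistant child stream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def substream_seed(seed: int, name: str) -> int:
    """A 31-bit integer seed derived from a named substream (for compiled kernels)."""
    return int(substream(seed, name).integers(0, 2**31 - 1))


@dataclass
class RunConfig:
    """Settings shared across pipeline stages.

    Parameters
    ----------
    seed : master seed; recorded in every output manifest.
    n_permutations : relabelings for the classifier permutation test.
    regularization_strength : C of the hinge-loss SVM.
    composite_cutoff : composite scores strictly below this are classified
        as the case group ("lower than 0.5" rule; exactly 0.5 is control).
    voxelwise_thresholds : strictly decreasing per-node significance levels
        for the multi-threshold robustness map.
    cluster_calibration_iters : permutations used to calibrate cluster
        extent thresholds.
    bonferroni_n : number of ROI interaction tests sharing the 0.05 budget.
    fisher_z_averaging : average atanh(r) instead of raw r in connectedness.
    case_label : which group label is the case (autism-analog) group.
    """

    seed: int = 0
    n_permutations: int = 1000
    regularization_strength: float = 1.0
    composite_cutoff: float = 0.5
    voxelwise_thresholds: Sequence[float] = DEFAULT_THRESHOLDS
    cluster_calibration_iters: int = 200
    bonferroni_n: int = 3
    fisher_z_averaging: bool = False
    case_label: str = "case"
    control_label: str = "control"
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be a positive integer")
        if self.regularization_strength <= 0:
            raise ValueError("regularization_strength must be positive")
        if not 0.0 <= self.composite_cutoff <= 1.0:
            raise ValueError("composite_cutoff must lie in [0, 1]")
        thr = tuple(float(t) for t in self.voxelwise_thresholds)
        if not thr or any(not 0.0 < t < 1.0 for t in thr):
            raise ValueError("voxelwise thresholds must lie strictly in (0, 1)")
        if any(b >= a for a, b in zip(thr, thr[1:])):
            raise ValueError("voxelwise thresholds must be strictly decreasing")
        self.voxelwise_thresholds = thr
        if self.cluster_calibration_iters < 1:
            raise ValueError("cluster_calibration_iters must be positive")
        if self.bonferroni_n < 1:
            raise ValueError("bonferroni_n must be a positive integer")
        if self.case_label == self.control_label:
            raise ValueError("case and control labels must differ")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["voxelwise_thresholds"] = list(self.voxelwise_thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def rng(self, stage: str) -> np.random.Generator:
        return substream(self.seed, stage)
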