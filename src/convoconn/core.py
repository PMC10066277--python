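"""Core in-memory containers shared by the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

META_COLUMNS = ("conversation_id", "participant_id", "group")


@dataclass
class FeatureTable:
    """Per-conversation linguistic feature vectors with participant metadata.

    ``data`` holds one row per conversation with the three metadata columns
    (conversation_id, participant_id, group) followed by numeric feature
    columns.  Group must take exactly two values across the table, and each
    participant belongs to exactly one group.
    """

    data: pd.DataFrame
    feature_columns: tuple[str, ...]

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature table missing required columns: {missing}")
        if len(self.feature_columns) < 1:
            raise ValueError("feature table needs at least one feature column")
        groups = self.data["group"].unique()
        if len(groups) != 2:
            raise ValueError(f"feature table must contain exactly 2 groups, found {len(groups)}")
        per_part = self.data.groupby("participant_id")["group"].nunique()
        if (per_part > 1).any():
            bad = per_part[per_part > 1].index.tolist()
            raise ValueError(f"participants mapped to more than one group: {bad}")

    @property
    def n_conversations(self) -> int:
        return len(self.data)

    @property
    def features(self) -> np.ndarray:
        return self.data[list(self.feature_columns)].to_numpy(dtype=float)

    def roster(self) -> pd.DataFrame:
        """participant_id -> group, one row per participant."""
        return (
            self.data[["participant_id", "group"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )

    def with_data(self, data: pd.DataFrame) -> "FeatureTable":
        return FeatureTable(data=data.reset_index(drop=True), feature_columns=self.feature_columns)


@dataclass
class ScanTimeSeries:
    """One conversation scan: nodes x timepoints signal plus covariates.

    ``nodes`` carries node_id, hemisphere in {L, R} and optional x/y/z
    coordinates, aligned row-for-row with ``data``.
    """

    scan_id: str
    participant_id: str
    data: np.ndarray
    nodes: pd.DataFrame
    age: float
    motion: float
    group: Optional[str] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("scan matrix must be 2-D (nodes x timepoints)")
        if self.data.shape[0] != len(self.nodes):
            raise ValueError(
                f"scan {self.scan_id}: matrix has {self.data.shape[0]} nodes but "
                f"metadata has {len(self.nodes)} rows"
            )
        if self.data.shape[0] < 2:
            raise ValueError("scan needs at least 2 nodes")
        if self.data.shape[1] < 2:
            raise ValueError("scan needs at least 2 timepoints")
        if "node_id" not in self.nodes.columns:
            raise ValueError("node metadata must include a node_id column")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def node_ids(self) -> list[str]:
        return self.nodes["node_id"].astype(str).tolist()

    def constant_nodes(self) -> np.ndarray:
        """Boolean mask of zero-variance nodes (flagged, not fatal)."""
        return self.data.std(axis=1) == 0.0


@dataclass
class ConnectednessMap:
    """Per-node mean correlation with all other nodes for one scan.

    ``scale`` is "r" for averaged raw correlations (values in [-1, 1]) or
    "z" when Fisher-transformed correlations were averaged (unbounded).
    Maps on different scales must not be mixed within one contrast.
    """

    scan_id: str
    participant_id: str
    node_ids: tuple[str, ...]
    values: np.ndarray
    scale: str = "r"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.node_ids),):
            raise ValueError("connectedness values must align with node ids")
        if self.scale not in ("r", "z"):
            raise ValueError("scale must be 'r' or 'z'")
        if self.scale == "r":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and np.abs(finite).max() > 1.0 + 1e-12:
                raise ValueError("raw-r connectedness values must lie in [-1, 1]")


@dataclass
class ROISet:
    """Named node sets with selection provenance."""

    rois: dict[str, tuple[str, ...]]
    provenance: dict[str, dict] = field(default_factory=dict)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.rois[name]

    def __len__(self) -> int:
        return len(self.rois)

    def names(self) -> list[str]:
        return list(self.rois)


def maps_to_wide(maps: Sequence[ConnectednessMap]) -> pd.DataFrame:
    """Stack maps into a scans x nodes frame (index scan_id, participant_id)."""
    if not maps:
        raise ValueError("no maps provided")
    scales = {m.scale for m in maps}
    if len(scales) > 1:
        raise ValueError("cannot mix raw-r and Fisher-z maps in one analysis")
    node_ids = maps[0].node_ids
    for m in maps:
        if m.node_ids != node_ids:
            raise ValueError(f"map {m.scan_id} has mismatched node ids")
    frame = pd.DataFrame(
        np.vstack([m.values for m in maps]),
        columns=list(node_ids),
    )
    frame.insert(0, "participant_id", [m.participant_id for m in maps])
    frame.insert(0, "scan_id", [m.scan_id for m in maps])
    frame.attrs["scale"] = maps[0].scale
    return frame
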