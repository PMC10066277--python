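"""Table and map readers/writers.

All tables are UTF-8, tab-delimited text with a header row; reals are
printed in full-precision scientific notation so read -> write -> read
round-trips are lossless to float64 resolution.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .core import META_COLUMNS, ConnectednessMap, FeatureTable, ScanTimeSeries

logger = logging.getLogger("convoconn")

FLOAT_FORMAT = "%.17g"


class FormatError(ValueError):
    """Structural problem in an input file."""


class ParseError(ValueError):
    """A cell could not be parsed; names the offending row/column."""


def _read_tsv(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def _write_tsv(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_feature_table(path: Union[str, Path]) -> FeatureTable:
    """Read a per-conversation feature table.

    Expects columns conversation_id, participant_id, group followed by one
    or more numeric feature columns; exactly two group labels.
    """
    raw = _read_tsv(path)
    missing = [c for c in META_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    feature_cols = [c for c in raw.columns if c not in META_COLUMNS]
    if not feature_cols:
        raise FormatError(f"{path}: no feature columns found")
    parsed = raw.copy()
    for col in feature_cols:
        try:
            # str -> float via the correctly-rounded parser so that
            # full-precision writes round-trip bit-identically
            parsed[col] = raw[col].astype(np.float64)
        except (ValueError, TypeError):
            bad = pd.to_numeric(raw[col], errors="coerce")
            row = int(bad[bad.isna() & raw[col].notna()].index[0])
            raise ParseError(
                f"{path}: non-numeric value {raw[col].iloc[row]!r} in column "
                f"{col!r}, row {row + 2} (1-based, counting the header)"
            ) from None
    table = FeatureTable(data=parsed, feature_columns=tuple(feature_cols))
    logger.info(
        "read %s: %d conversations, %d features, groups %s",
        path, table.n_conversations, len(feature_cols),
        sorted(parsed["group"].unique()),
    )
    return table


def write_feature_table(table: FeatureTable, path: Union[str, Path]) -> None:
    _write_tsv(table.data, path)


def apply_exclusions(
    obj: Union[FeatureTable, Sequence[ScanTimeSeries]],
    excluded_ids: Iterable[str],
) -> Union[FeatureTable, list[ScanTimeSeries]]:
    """Drop excluded conversations from a feature table or scan collection.

    The same conversation-id list applies to both behavioral and brain data
    (scan ids equal conversation ids).  Unknown ids produce a warning, not
    an error.
    """
    excluded = {str(e) for e in excluded_ids}
    if isinstance(obj, FeatureTable):
        present = set(obj.data["conversation_id"].astype(str))
        unknown = excluded - present
        if unknown:
            warnings.warn(f"exclusion ids not present in table: {sorted(unknown)}")
        keep = obj.data[~obj.data["conversation_id"].astype(str).isin(excluded)]
        if keep["group"].nunique() < 2:
            raise ValueError("exclusions removed an entire group from the table")
        logger.info(
            "excluded %d conversations, %d remaining",
            len(obj.data) - len(keep), len(keep),
        )
        return obj.with_data(keep)
    scans = list(obj)
    present = {s.scan_id for s in scans}
    unknown = excluded - present
    if unknown:
        warnings.warn(f"exclusion ids not present in scan collection: {sorted(unknown)}")
    kept = [s for s in scans if s.scan_id not in excluded]
    logger.info("excluded %d scans, %d remaining", len(scans) - len(kept), len(kept))
    return kept


def read_node_metadata(path: Union[str, Path]) -> pd.DataFrame:
    nodes = _read_tsv(path)
    if "node_id" not in nodes.columns:
        raise FormatError(f"{path}: node metadata must have a node_id column")
    if "hemisphere" in nodes.columns:
        bad = set(nodes["hemisphere"].dropna().unique()) - {"L", "R"}
        if bad:
            raise FormatError(f"{path}: hemisphere labels must be L or R, found {sorted(bad)}")
    for col in ("x", "y", "z"):
        if col in nodes.columns:
            nodes[col] = pd.to_numeric(nodes[col], errors="raise")
    return nodes


def read_scan_timeseries(
    path: Union[str, Path],
    metadata_path: Union[str, Path],
    scan_id: str | None = None,
    participant_id: str = "",
    age: float = float("nan"),
    motion: float = float("nan"),
    group: str | None = None,
) -> ScanTimeSeries:
    """Read a nodes x timepoints matrix and its node metadata."""
    matrix = pd.read_csv(
        path, sep="\t", header=None, float_precision="round_trip"
    ).to_numpy(dtype=float)
    nodes = read_node_metadata(metadata_path)
    if matrix.shape[0] != len(nodes):
        raise FormatError(
            f"{path}: matrix has {matrix.shape[0]} node rows but metadata "
            f"{metadata_path} has {len(nodes)}"
        )
    scan = ScanTimeSeries(
        scan_id=scan_id or Path(path).stem,
        participant_id=participant_id,
        data=matrix,
        nodes=nodes,
        age=age,
        motion=motion,
        group=group,
    )
    n_const = int(scan.constant_nodes().sum())
    if n_const:
        logger.warning("scan %s: %d constant (zero-variance) nodes flagged", scan.scan_id, n_const)
    logger.info("read scan %s: %d nodes x %d timepoints", scan.scan_id, scan.n_nodes, scan.n_timepoints)
    return scan


def write_scan_timeseries(scan: ScanTimeSeries, path: Union[str, Path]) -> None:
    pd.DataFrame(scan.data).to_csv(path, sep="\t", index=False, header=False,
                                   float_format=FLOAT_FORMAT)


def read_scan_collection(
    scans_dir: Union[str, Path],
    metadata_path: Union[str, Path],
    covariates_path: Union[str, Path],
) -> list[ScanTimeSeries]:
    """Read all scans listed in a covariates table from a directory.

    The covariates table needs columns scan_id, participant_id, group, age,
    motion; each scan_id maps to <scans_dir>/<scan_id>.tsv.
    """
    cov = _read_tsv(covariates_path)
    required = ["scan_id", "participant_id", "group", "age", "motion"]
    missing = [c for c in required if c not in cov.columns]
    if missing:
        raise FormatError(f"{covariates_path}: missing columns {missing}")
    scans = []
    for _, row in cov.iterrows():
        scans.append(
            read_scan_timeseries(
                Path(scans_dir) / f"{row['scan_id']}.tsv",
                metadata_path,
                scan_id=str(row["scan_id"]),
                participant_id=str(row["participant_id"]),
                age=float(row["age"]),
                motion=float(row["motion"]),
                group=str(row["group"]),
            )
        )
    return scans


def write_map(
    map_frame: Union[ConnectednessMap, pd.DataFrame],
    path: Union[str, Path],
    format: str = "tsv",
    nodes: pd.DataFrame | None = None,
    value_column: str = "value",
) -> None:
    """Write a per-node map as TSV (canonical) or NIfTI (optional sugar).

    NIfTI output needs integer-castable x/y/z node coordinates in ``nodes``;
    values are placed on the regular grid spanned by the coordinates.
    """
    if isinstance(map_frame, ConnectednessMap):
        frame = pd.DataFrame({"node_id": map_frame.node_ids, value_column: map_frame.values})
    else:
        frame = map_frame
    if format == "tsv":
        _write_tsv(frame, path)
        return
    if format == "nifti":
        if nodes is None or not {"x", "y", "z"}.issubset(nodes.columns):
            raise ValueError("NIfTI export requires node coordinates (x, y, z)")
        import nibabel as nib

        meta = nodes.set_index(nodes["node_id"].astype(str))
        coords = meta.loc[frame["node_id"].astype(str), ["x", "y", "z"]].to_numpy(dtype=float)
        ijk = np.round(coords - coords.min(axis=0)).astype(int)
        shape = ijk.max(axis=0) + 1
        vol = np.zeros(shape, dtype=np.float64)
        vol[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = frame[value_column].to_numpy(dtype=float)
        affine = np.eye(4)
        affine[:3, 3] = coords.min(axis=0)
        nib.save(nib.Nifti1Image(vol, affine), str(path))
        return
    raise ValueError(f"unknown map format {format!r}")


def read_map(path: Union[str, Path], value_column: str = "value") -> pd.DataFrame:
    frame = _read_tsv(path)
    frame[value_column] = pd.to_numeric(frame[value_column], errors="raise")
    return frame


def sha256_of(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    path: Union[str, Path],
    config: dict,
    inputs: Iterable[Union[str, Path]] = (),
    extra: dict | None = None,
) -> None:
    """Record config, seed, input hashes and versions alongside outputs."""
    from . import __version__

    manifest = {
        "package": "convoconn",
        "version": __version__,
        "config": config,
        "inputs": {str(p): sha256_of(p) for p in inputs},
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
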