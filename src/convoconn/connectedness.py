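"""Whole-brain connectedness maps, group contrast, and robustness/ROI logic.

Connectedness of a node is the mean Pearson correlation of its time series
with every other node's — a weighted-degree-like summary of global
functional involvement, computed per scan.  Maps are contrasted between
groups with a per-node linear mixed model (random intercept per
participant, age and motion as nuisance covariates), thresholded at a
descending ladder of per-node significance levels combined with
permutation-calibrated cluster extents, and the nodes surviving every
rung are grouped into ROIs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .config import substream
from .core import ConnectednessMap, ROISet, ScanTimeSeries, maps_to_wide

logger = logging.getLogger("convoconn")

__all__ = [
    "compute_connectedness",
    "fit_group_contrast",
    "adjacency_from_coordinates",
    "adjacency_from_edges",
    "find_clusters",
    "calibrate_cluster_extent",
    "extent_table",
    "build_robustness_map",
    "select_rois",
    "RobustnessMap",
]


def compute_connectedness(scan: ScanTimeSeries, fisher_z: bool = False) -> ConnectednessMap:
    """Mean correlation of each node with all other nodes.

    Step 1: correlate every node with every other node; step 2: average
    those correlations; step 3: store the average at the node.  With
    ``fisher_z`` the correlations are atanh-transformed before averaging
    and the map is reported on the z scale (no back-transform).

    Constant (zero-variance) nodes receive NaN and are excluded from the
    averages of the remaining nodes.
    """
    if scan.n_timepoints < 3:
        raise ValueError(f"scan {scan.scan_id}: need >= 3 timepoints for correlation")
    const = scan.constant_nodes()
    n = scan.n_nodes
    values = np.full(n, np.nan)
    valid = ~const
    if const.any():
        logger.warning(
            "scan %s: %d constant node(s) excluded from connectedness",
            scan.scan_id, int(const.sum()),
        )
    nv = int(valid.sum())
    if nv >= 2:
        r = np.corrcoef(scan.data[valid])
        np.clip(r, -1.0, 1.0, out=r)
        if fisher_z:
            r = np.arctanh(np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15))
        np.fill_diagonal(r, 0.0)
        values[valid] = r.sum(axis=1) / (nv - 1)
    return ConnectednessMap(
        scan_id=scan.scan_id,
        participant_id=scan.participant_id,
        node_ids=tuple(scan.node_ids),
        values=values,
        scale="z" if fisher_z else "r",
    )


def _covariate_frame(covariates: pd.DataFrame) -> pd.DataFrame:
    required = ["scan_id", "participant_id", "group", "age", "motion"]
    missing = [c for c in required if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariates table missing columns {missing}")
    out = covariates.copy()
    out["age"] = pd.to_numeric(out["age"])
    out["motion"] = pd.to_numeric(out["motion"])
    return out


def _design(merged: pd.DataFrame, case_label: str, include_covariates: bool = True) -> np.ndarray:
    group = (merged["group"].astype(str) == case_label).astype(float).to_numpy()
    cols = [np.ones(len(merged)), group]
    if include_covariates:
        for name in ("age", "motion"):
            v = merged[name].to_numpy(dtype=float)
            if np.ptp(v) > 0:  # constant covariates carry no information
                cols.append(v)
    return np.column_stack(cols)


def ols_contrast(
    Y: np.ndarray, X: np.ndarray, coef_index: int = 1
) -> tuple[np.ndarray, np.ndarray, int, np.ndarray]:
    """Vectorized OLS over map columns; returns (estimates, t, df, two-sided p)."""
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y
    resid = Y - X @ B
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(XtX_inv[coef_index, coef_index] * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = B[coef_index] / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return B[coef_index], t, df, pvals


def _participant_means(
    wide: pd.DataFrame, cov: pd.DataFrame, node_cols: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    merged = wide.merge(
        cov[["scan_id", "group", "age", "motion"]], on="scan_id", validate="one_to_one"
    )
    agg = merged.groupby("participant_id", sort=True).agg(
        {**{c: "mean" for c in node_cols}, "age": "mean", "motion": "mean", "group": "first"}
    )
    return agg[list(node_cols)], agg[["group", "age", "motion"]]


def fit_group_contrast(
    maps: Sequence[ConnectednessMap] | pd.DataFrame,
    covariates: pd.DataFrame,
    case_label: str = "case",
    engine: str = "mixedlm",
    df_method: str = "participant",
) -> pd.DataFrame:
    """Per-node case-minus-control contrast of connectedness maps.

    Default engine fits, for every node, the scan-level mixed model
    value ~ group + age + motion with a per-participant random intercept
    (REML; the package's profiled-REML solver — ``engine="statsmodels"``
    fits the identical model through MixedLM for cross-checking).
    ``engine="ols"`` instead regresses participant-mean maps on the same
    fixed effects — also the automatic fallback when a node's mixed fit
    fails.  ``df_method`` picks the t-test reference dfs:
    "participant" (n_participants - n_fixed, the convention that matches
    participant-level reporting) or "residual" (n_obs - n_fixed).

    Returns one row per node: estimate, t, df, p (two-sided),
    p_one_sided (case > control), fallback flag.
    """
    wide = maps if isinstance(maps, pd.DataFrame) else maps_to_wide(maps)
    cov = _covariate_frame(covariates)
    node_cols = [c for c in wide.columns if c not in ("scan_id", "participant_id")]
    merged = wide.merge(
        cov[["scan_id", "group", "age", "motion"]], on="scan_id", validate="one_to_one"
    )
    if merged["group"].nunique() != 2:
        raise ValueError("both groups must be present in the contrast")
    n_participants = merged["participant_id"].nunique()
    if engine == "ols":
        Ymeans, pdesign = _participant_means(wide, cov, node_cols)
        X = _design(pdesign, case_label)
        est, t, dof, pvals = ols_contrast(Ymeans.to_numpy(dtype=float), X)
        fallback = np.zeros(len(node_cols), dtype=bool)
    elif engine in ("mixedlm", "statsmodels"):
        from ._lmm import reml_random_intercept

        X = _design(merged, case_label)
        groups_arr = merged["participant_id"].to_numpy()
        est = np.empty(len(node_cols))
        t = np.empty(len(node_cols))
        fallback = np.zeros(len(node_cols), dtype=bool)
        Ymeans, pdesign = _participant_means(wide, cov, node_cols)
        Xp = _design(pdesign, case_label)
        for j, col in enumerate(node_cols):
            y = merged[col].to_numpy(dtype=float)
            ok = np.isfinite(y)
            try:
                if engine == "statsmodels":
                    import statsmodels.api as sm

                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = sm.MixedLM(
                            y[ok], X[ok], groups=groups_arr[ok]
                        ).fit(reml=True)
                        est[j] = res.fe_params[1]
                        t[j] = res.fe_params[1] / res.bse_fe[1]
                else:
                    beta, se, _, _ = reml_random_intercept(y[ok], X[ok], groups_arr[ok])
                    est[j] = beta[1]
                    t[j] = beta[1] / se[1]
                if not np.isfinite(est[j]) or not np.isfinite(t[j]):
                    raise ValueError("non-finite mixed-model fit")
            except Exception:
                fallback[j] = True
                e1, t1, _, _ = ols_contrast(
                    Ymeans[[col]].to_numpy(dtype=float), Xp
                )
                est[j], t[j] = e1[0], t1[0]
        p_fixed = X.shape[1]
        dof = (
            n_participants - p_fixed
            if df_method == "participant"
            else len(merged) - p_fixed
        )
        pvals = 2.0 * stats.t.sf(np.abs(t), dof)
        if fallback.any():
            logger.warning(
                "mixed-model fit fell back to participant-mean OLS for %d node(s)",
                int(fallback.sum()),
            )
    else:
        raise ValueError(f"unknown engine {engine!r}")
    with np.errstate(invalid="ignore"):
        p_one = np.where(est > 0, pvals / 2.0, 1.0 - pvals / 2.0)
    return pd.DataFrame(
        {
            "node_id": node_cols,
            "estimate": est,
            "t": t,
            "df": dof,
            "p": pvals,
            "p_one_sided": p_one,
            "fallback_ols": fallback,
        }
    )


def adjacency_from_coordinates(nodes: pd.DataFrame, radius: float = 1.5) -> sparse.csr_matrix:
    """Symmetric adjacency: nodes within ``radius`` Euclidean distance."""
    for col in ("x", "y", "z"):
        if col not in nodes.columns:
            raise ValueError("coordinate adjacency needs x, y, z columns")
    xyz = nodes[["x", "y", "z"]].to_numpy(dtype=float)
    d2 = ((xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(-1)
    adj = (d2 <= radius**2) & (d2 > 0)
    return sparse.csr_matrix(adj)


def adjacency_from_edges(edges: pd.DataFrame, node_ids: Sequence[str]) -> sparse.csr_matrix:
    """Adjacency from an edge list with columns node_a, node_b."""
    index = {str(n): i for i, n in enumerate(node_ids)}
    n = len(node_ids)
    rows, cols = [], []
    for _, e in edges.iterrows():
        a, b = index[str(e["node_a"])], index[str(e["node_b"])]
        rows += [a, b]
        cols += [b, a]
    return sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))


def find_clusters(mask: np.ndarray, adjacency: sparse.spmatrix) -> list[np.ndarray]:
    """Connected components of the supra-threshold subgraph, largest first."""
    mask = np.asarray(mask, dtype=bool)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    sub = adjacency[np.ix_(idx, idx)]
    if (sub != sub.T).nnz:
        raise ValueError("adjacency must be symmetric")
    n_comp, labels = connected_components(sub, directed=False)
    clusters = [idx[labels == c] for c in range(n_comp)]
    clusters.sort(key=len, reverse=True)
    return clusters


def extent_table(thresholds: Sequence[float], ks: Sequence[int]) -> pd.DataFrame:
    """Build an extent table from externally supplied cluster sizes."""
    if len(thresholds) != len(ks):
        raise ValueError("one k per threshold required")
    tab = pd.DataFrame({"alpha": list(thresholds), "k": [int(k) for k in ks]})
    if (np.diff(tab["k"]) > 0).any():
        raise ValueError("k must be non-increasing as alpha decreases")
    return tab


def calibrate_cluster_extent(
    maps: Sequence[ConnectednessMap] | pd.DataFrame,
    covariates: pd.DataFrame,
    adjacency: sparse.spmatrix,
    thresholds: Sequence[float],
    n_iter: int = 200,
    seed: int = 0,
    alpha_fw: float = 0.05,
    case_label: str = "case",
) -> pd.DataFrame:
    """Permutation calibration of minimum cluster sizes.

    For each per-node threshold, group labels are permuted across
    participants, the one-sided contrast map is recomputed (participant-
    mean OLS null engine), and the largest supra-threshold cluster size is
    recorded; k is the smallest extent whose exceedance probability
    P(max cluster size >= k) falls at or below ``alpha_fw`` (capped at the
    node count when even that cannot be controlled, e.g. alpha -> 1).  The
    returned table is made monotone (k non-increasing as the threshold
    tightens) by cumulative minimum.
    """
    if n_iter < int(round(1.0 / alpha_fw)) * 5:
        raise ValueError(
            f"n_iter={n_iter} too small to estimate the {1 - alpha_fw:.0%} percentile"
        )
    thresholds = [float(a) for a in thresholds]
    wide = maps if isinstance(maps, pd.DataFrame) else maps_to_wide(maps)
    cov = _covariate_frame(covariates)
    node_cols = [c for c in wide.columns if c not in ("scan_id", "participant_id")]
    Ymeans, pdesign = _participant_means(wide, cov, node_cols)
    Y = Ymeans.to_numpy(dtype=float)
    base_group = (pdesign["group"].astype(str) == case_label).to_numpy(dtype=float)
    age = pdesign["age"].to_numpy(dtype=float)
    motion = pdesign["motion"].to_numpy(dtype=float)
    rng = substream(seed, "cluster-extent")
    max_sizes = np.zeros((n_iter, len(thresholds)), dtype=int)
    ones = np.ones(len(base_group))
    covariate_cols = [v for v in (age, motion) if np.ptp(v) > 0]
    for b in range(n_iter):
        gperm = rng.permutation(base_group)
        X = np.column_stack([ones, gperm, *covariate_cols])
        est, tvals, dof, pvals = ols_contrast(Y, X)
        p_one = np.where(est > 0, pvals / 2.0, 1.0 - pvals / 2.0)
        for a_i, alpha in enumerate(thresholds):
            clusters = find_clusters(p_one < alpha, adjacency)
            max_sizes[b, a_i] = len(clusters[0]) if clusters else 0
    n_nodes = len(node_cols)
    ks = np.empty(len(thresholds), dtype=int)
    for a_i in range(len(thresholds)):
        sizes = max_sizes[:, a_i]
        k = 1
        while k <= n_nodes and (sizes >= k).mean() > alpha_fw:
            k += 1
        # cap at the node count: in the degenerate all-significant regime no
        # extent can control the familywise rate, so the largest possible
        # cluster size is required instead
        ks[a_i] = min(k, n_nodes)
    ks = np.maximum(np.minimum.accumulate(ks), 1)
    return pd.DataFrame({"alpha": thresholds, "k": ks})


@dataclass
class RobustnessMap:
    """Per node, the most stringent threshold rung survived (0 = none)."""

    node_ids: tuple[str, ...]
    max_index: np.ndarray
    survived: np.ndarray  # (n_thresholds, n_nodes) boolean
    thresholds: tuple[float, ...]
    extents: tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"node_id": self.node_ids, "max_threshold_index": self.max_index})


def build_robustness_map(
    contrast: pd.DataFrame,
    thresholds: Sequence[float],
    extents: pd.DataFrame,
    adjacency: sparse.spmatrix,
) -> RobustnessMap:
    """Binarize-and-combine across the threshold ladder.

    Thresholds are ordered least to most stringent; a node survives rung i
    when its one-sided (case > control) p beats alpha_i *and* it sits in a
    supra-threshold cluster of at least k_i nodes.  The map stores the most
    stringent rung survived per node.
    """
    thresholds = [float(a) for a in thresholds]
    ext = extents.set_index("alpha")["k"]
    missing = [a for a in thresholds if a not in ext.index]
    if missing:
        raise ValueError(f"extent table missing thresholds {missing}")
    p_one = contrast["p_one_sided"].to_numpy(dtype=float)
    n_nodes = len(contrast)
    survived = np.zeros((len(thresholds), n_nodes), dtype=bool)
    for i, alpha in enumerate(thresholds):
        k = int(ext.loc[alpha])
        for cluster in find_clusters(p_one < alpha, adjacency):
            if len(cluster) >= k:
                survived[i, cluster] = True
    max_index = np.zeros(n_nodes, dtype=int)
    for i in range(len(thresholds)):
        max_index[survived[i]] = i + 1
    return RobustnessMap(
        node_ids=tuple(contrast["node_id"].astype(str)),
        max_index=max_index,
        survived=survived,
        thresholds=tuple(thresholds),
        extents=tuple(int(ext.loc[a]) for a in thresholds),
    )


def select_rois(
    robustness: RobustnessMap,
    adjacency: sparse.spmatrix,
    min_size: int = 10,
    name_prefix: str = "roi",
) -> ROISet:
    """Connected clusters of nodes that survived every threshold rung.

    Clusters below ``min_size`` nodes are discarded (the >= 10-voxel rule
    at the selection threshold).  An empty ROISet is a legitimate outcome.
    """
    all_survived = robustness.survived.all(axis=0)
    clusters = [c for c in find_clusters(all_survived, adjacency) if len(c) >= min_size]
    rois = {}
    provenance = {}
    node_ids = np.asarray(robustness.node_ids)
    for i, cluster in enumerate(clusters):
        name = f"{name_prefix}_{i + 1}"
        rois[name] = tuple(node_ids[cluster])
        provenance[name] = {
            "size": int(len(cluster)),
            "thresholds_survived": len(robustness.thresholds),
            "min_size": int(min_size),
        }
    logger.info("selected %d ROI(s) surviving all %d thresholds", len(rois), len(robustness.thresholds))
    return ROISet(rois=rois, provenance=provenance)
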