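"""Per-ROI compensation test and seed-based follow-up.

The compensation signature: regressing ROI connectedness on the language
classifier score, group, and their interaction, a significantly more
positive score slope in the case group (interaction coded control-minus-
case, hence negative under compensation) indicates that elevated
connectivity tracks more typical behavior only where it is needed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .connectedness import (
    _covariate_frame,
    calibrate_cluster_extent,
    find_clusters,
    fit_group_contrast,
)
from .core import ConnectednessMap, ScanTimeSeries, maps_to_wide

logger = logging.getLogger("convoconn")

__all__ = [
    "roi_connectedness",
    "fit_interaction",
    "per_group_correlation",
    "bonferroni",
    "seed_connectivity_map",
    "seed_group_contrast",
    "CompensationResult",
    "SeedContrastResult",
]


def bonferroni(alpha: float = 0.05, n_tests: int = 3) -> float:
    """Corrected per-test alpha; exact internally, round only for display."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def roi_connectedness(
    maps: Sequence[ConnectednessMap] | pd.DataFrame,
    roi: Sequence[str],
    aggregate_participant: bool = False,
) -> pd.DataFrame:
    """Mean connectedness over the ROI's nodes, per scan or per participant."""
    roi = [str(r) for r in roi]
    if not roi:
        raise ValueError("ROI must be nonempty")
    wide = maps if isinstance(maps, pd.DataFrame) else maps_to_wide(maps)
    missing = [r for r in roi if r not in wide.columns]
    if missing:
        raise ValueError(f"ROI nodes missing from maps: {missing}")
    vals = wide[roi].to_numpy(dtype=float)
    if np.isnan(vals).any():
        bad = wide.loc[np.isnan(vals).any(axis=1), "scan_id"].tolist()
        raise ValueError(f"ROI contains missing node values in scans {bad}")
    out = pd.DataFrame(
        {
            "scan_id": wide["scan_id"],
            "participant_id": wide["participant_id"],
            "value": vals.mean(axis=1),
        }
    )
    if aggregate_participant:
        out = (
            out.groupby("participant_id", sort=True)["value"]
            .mean()
            .reset_index()
        )
    return out


@dataclass
class CompensationResult:
    roi: str
    interaction_estimate: float
    interaction_t: float
    interaction_df: int
    interaction_p: float
    case_slope: float
    control_slope: float
    case_r: Optional[tuple[float, int, float]] = None  # (r, df, p)
    control_r: Optional[tuple[float, int, float]] = None
    bonferroni_alpha: float = 0.05 / 3
    model: str = ""

    @property
    def passes_bonferroni(self) -> bool:
        return self.interaction_p < self.bonferroni_alpha


def fit_interaction(
    roi_values: pd.DataFrame,
    composites: pd.DataFrame,
    covariates: pd.DataFrame,
    case_label: str = "case",
    level: str = "scan",
    include_covariates: bool = True,
    bonferroni_alpha: float = 0.05 / 3,
    roi_name: str = "roi",
    with_correlations: bool = True,
) -> CompensationResult:
    """Connectivity ~ Score + Group + Score x Group (+ Age + Motion).

    Group is coded 1 = control, so the interaction term is the control
    slope minus the case slope: compensation (a steeper positive score
    slope in the case group) appears as a *negative* interaction.

    ``level="scan"`` fits all scans with a per-participant random
    intercept (REML; t referred to participant-level dfs);
    ``level="participant"`` aggregates to participant means and fits OLS,
    whose dfs equal n_participants minus the number of fixed effects.
    """
    cov = _covariate_frame(covariates)
    merged = roi_values.merge(
        cov[["scan_id", "group", "age", "motion"]], on="scan_id", how="left"
    ) if "scan_id" in roi_values.columns else roi_values.copy()
    comp = composites[["participant_id", "composite", "true_group"]]
    merged = merged.merge(comp, on="participant_id", validate="many_to_one")
    for grp, sub in merged.groupby("true_group"):
        if sub["participant_id"].nunique() < 3:
            raise ValueError(f"need >= 3 participants in group {grp!r}")
        if sub["composite"].nunique() < 2:
            raise ValueError(f"classifier score constant within group {grp!r}")
    if level == "participant":
        agg = merged.groupby("participant_id", sort=True).agg(
            value=("value", "mean"),
            composite=("composite", "first"),
            true_group=("true_group", "first"),
            age=("age", "mean"),
            motion=("motion", "mean"),
        )
        y = agg["value"].to_numpy(dtype=float)
        score = agg["composite"].to_numpy(dtype=float)
        ctrl = (agg["true_group"].astype(str) != case_label).astype(float).to_numpy()
        cols = [np.ones(len(agg)), score, ctrl, score * ctrl]
        if include_covariates:
            cols += [agg["age"].to_numpy(dtype=float), agg["motion"].to_numpy(dtype=float)]
        X = np.column_stack(cols)
        n, p = X.shape
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        resid = y - X @ beta
        df = n - p
        sigma2 = float(resid @ resid) / df
        se = np.sqrt(sigma2 * XtX_inv[3, 3])
        t_int = float(beta[3] / se)
        model = "participant-mean OLS"
    elif level == "scan":
        from ._lmm import reml_random_intercept

        score = merged["composite"].to_numpy(dtype=float)
        ctrl = (merged["true_group"].astype(str) != case_label).astype(float).to_numpy()
        cols = [np.ones(len(merged)), score, ctrl, score * ctrl]
        if include_covariates:
            cols += [
                merged["age"].to_numpy(dtype=float),
                merged["motion"].to_numpy(dtype=float),
            ]
        X = np.column_stack(cols)
        y = merged["value"].to_numpy(dtype=float)
        beta, se, _, _ = reml_random_intercept(
            y, X, merged["participant_id"].to_numpy()
        )
        t_int = float(beta[3] / se[3])
        df = merged["participant_id"].nunique() - X.shape[1]
        model = "scan-level mixed model (participant random intercept, REML)"
    else:
        raise ValueError(f"unknown level {level!r}")
    p_int = float(2.0 * stats.t.sf(abs(t_int), df))
    case_slope = float(beta[1])
    control_slope = float(beta[1] + beta[3])
    result = CompensationResult(
        roi=roi_name,
        interaction_estimate=float(beta[3]),
        interaction_t=t_int,
        interaction_df=int(df),
        interaction_p=p_int,
        case_slope=case_slope,
        control_slope=control_slope,
        bonferroni_alpha=bonferroni_alpha,
        model=model + (" + age + motion" if include_covariates else ""),
    )
    if with_correlations:
        agg = merged.groupby("participant_id", sort=True).agg(
            value=("value", "mean"),
            composite=("composite", "first"),
            true_group=("true_group", "first"),
        )
        for grp_attr, is_case in (("case_r", True), ("control_r", False)):
            sub = agg[(agg["true_group"].astype(str) == case_label) == is_case]
            setattr(
                result,
                grp_attr,
                per_group_correlation(
                    sub["value"].to_numpy(dtype=float),
                    sub["composite"].to_numpy(dtype=float),
                ),
            )
    return result


def per_group_correlation(values: np.ndarray, scores: np.ndarray) -> tuple[float, int, float]:
    """Participant-level Pearson correlation; returns (r, df=n-2, two-sided p)."""
    values = np.asarray(values, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if len(values) < 4:
        raise ValueError("need >= 4 participants for a per-group correlation")
    if values.std() == 0.0 or scores.std() == 0.0:
        raise ValueError("zero variance in correlation input")
    r, p = stats.pearsonr(values, scores)
    return float(r), len(values) - 2, float(p)


def seed_connectivity_map(scan: ScanTimeSeries, seed_roi: Sequence[str]) -> ConnectednessMap:
    """Correlation of every non-seed node with the mean seed time series.

    Seed nodes carry NaN in the output map.
    """
    seed_roi = [str(s) for s in seed_roi]
    node_ids = scan.node_ids
    seed_mask = np.isin(node_ids, seed_roi)
    if seed_mask.sum() != len(set(seed_roi)):
        missing = set(seed_roi) - set(node_ids)
        raise ValueError(f"seed nodes missing from scan {scan.scan_id}: {sorted(missing)}")
    seed_signal = scan.data[seed_mask].mean(axis=0)
    if seed_signal.std() == 0.0:
        raise ValueError(f"scan {scan.scan_id}: constant seed signal")
    values = np.full(scan.n_nodes, np.nan)
    target = ~seed_mask
    sd = scan.data[target].std(axis=1)
    ok = sd > 0
    centered = scan.data[target] - scan.data[target].mean(axis=1, keepdims=True)
    s_centered = seed_signal - seed_signal.mean()
    r = np.full(int(target.sum()), np.nan)
    r[ok] = (centered[ok] @ s_centered) / (
        np.sqrt((centered[ok] ** 2).sum(axis=1)) * np.sqrt((s_centered**2).sum())
    )
    values[target] = np.clip(r, -1.0, 1.0)
    return ConnectednessMap(
        scan_id=scan.scan_id,
        participant_id=scan.participant_id,
        node_ids=tuple(node_ids),
        values=values,
        scale="r",
    )


@dataclass
class SeedContrastResult:
    contrast: pd.DataFrame
    significant_nodes: tuple[str, ...]
    left_count: int
    right_count: int
    ratio: float
    ratio_infinite: bool
    alpha: float
    k: int


def seed_group_contrast(
    seed_maps: Sequence[ConnectednessMap],
    covariates: pd.DataFrame,
    nodes: pd.DataFrame,
    adjacency: sparse.spmatrix,
    alpha: float = 0.001,
    k: Optional[int] = None,
    case_label: str = "case",
    engine: str = "mixedlm",
    calibration_iters: int = 200,
    seed: int = 0,
) -> SeedContrastResult:
    """Case > control contrast of seed-correlation maps with hemisphere counts.

    Seed-correlation values are Fisher-z transformed before model fitting
    (variance stabilization).  The significant set requires one-sided
    p < alpha within a surviving cluster of at least k nodes; when k is
    not supplied it is calibrated by group-label permutation at the same
    alpha.  Nodes without a hemisphere label are excluded from the counts
    (with a warning) but remain in the significant set.
    """
    wide = maps_to_wide(seed_maps)
    node_cols = [c for c in wide.columns if c not in ("scan_id", "participant_id")]
    z = np.arctanh(np.clip(wide[node_cols].to_numpy(dtype=float), -1 + 1e-15, 1 - 1e-15))
    zwide = wide.copy()
    zwide[node_cols] = z
    seed_nodes = [c for c in node_cols if np.isnan(z[:, node_cols.index(c)]).all()]
    analyzable = [c for c in node_cols if c not in seed_nodes]
    zsub = zwide[["scan_id", "participant_id"] + analyzable]
    contrast = fit_group_contrast(zsub, covariates, case_label=case_label, engine=engine)
    if k is None:
        ext = calibrate_cluster_extent(
            zsub, covariates,
            adjacency=_subset_adjacency(adjacency, node_cols, analyzable),
            thresholds=[alpha], n_iter=calibration_iters, seed=seed,
            case_label=case_label,
        )
        k = int(ext["k"].iloc[0])
    sub_adj = _subset_adjacency(adjacency, node_cols, analyzable)
    p_one = contrast["p_one_sided"].to_numpy(dtype=float)
    significant = np.zeros(len(analyzable), dtype=bool)
    for cluster in find_clusters(p_one < alpha, sub_adj):
        if len(cluster) >= k:
            significant[cluster] = True
    sig_nodes = tuple(np.asarray(analyzable)[significant])
    meta = nodes.set_index(nodes["node_id"].astype(str))
    hemis = []
    unlabeled = 0
    for nid in sig_nodes:
        h = meta.loc[nid].get("hemisphere") if nid in meta.index else None
        if h in ("L", "R"):
            hemis.append(h)
        else:
            unlabeled += 1
    if unlabeled:
        warnings.warn(f"{unlabeled} significant node(s) lack hemisphere labels; excluded from counts")
    left = hemis.count("L")
    right = hemis.count("R")
    if right == 0:
        ratio, inf = (float("inf") if left else float("nan")), left > 0
    else:
        ratio, inf = left / right, False
    logger.info(
        "seed contrast: %d significant nodes (L=%d, R=%d) at alpha=%g, k=%d",
        len(sig_nodes), left, right, alpha, k,
    )
    return SeedContrastResult(
        contrast=contrast,
        significant_nodes=sig_nodes,
        left_count=left,
        right_count=right,
        ratio=ratio,
        ratio_infinite=inf,
        alpha=alpha,
        k=int(k),
    )


def _subset_adjacency(
    adjacency: sparse.spmatrix, node_cols: Sequence[str], keep: Sequence[str]
) -> sparse.csr_matrix:
    idx = [node_cols.index(c) for c in keep]
    return sparse.csr_matrix(adjacency)[np.ix_(idx, idx)]
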