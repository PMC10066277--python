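"""Language-typicality phenotype: LOO linear SVM with Platt-calibrated scores.

The chain: z-score the per-conversation feature table, train an
L2-regularized hinge-loss linear classifier with each conversation held out
in turn, map the pooled cross-validated decision values to posterior
probabilities with a two-parameter sigmoid, average posteriors within
participant into a composite score (higher = more control-like), classify
by the 0.5-cutoff rule, and assess significance by participant-level label
permutation.  Validation surfaces: ROC/AUC of the composite and the
Spearman correlation of case-group composites with ordinal severity scores.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations as _iter_permutations
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import _svm
from .config import RunConfig, substream, substream_seed
from .core import FeatureTable

logger = logging.getLogger("convoconn")

__all__ = [
    "standardize",
    "loo_classify",
    "composite_scores",
    "evaluate_accuracy",
    "permutation_test",
    "validate_severity",
    "roc_analysis",
    "evaluate_classifier",
    "control_classifier",
    "ClassifierEvaluation",
    "PermutationResult",
]


def standardize(table: FeatureTable, ddof: int = 1) -> tuple[FeatureTable, dict]:
    """Z-score every feature column over the whole table.

    Constant (zero-variance) columns are dropped with a warning.  Returns
    the standardized table and the transformation parameters (per-column
    mean and SD) so the transform is recorded and reusable.
    """
    X = table.features
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    constant = sd == 0.0
    if constant.all():
        raise ValueError("all feature columns are constant; nothing to standardize")
    kept = [c for c, is_const in zip(table.feature_columns, constant) if not is_const]
    if constant.any():
        dropped = [c for c, is_const in zip(table.feature_columns, constant) if is_const]
        warnings.warn(f"dropping {len(dropped)} constant feature column(s): {dropped}")
    Z = (X[:, ~constant] - mean[~constant]) / sd[~constant]
    data = table.data[["conversation_id", "participant_id", "group"]].copy()
    data[kept] = Z
    params = {
        "columns": kept,
        "mean": mean[~constant].tolist(),
        "sd": sd[~constant].tolist(),
        "ddof": ddof,
        "dropped": [c for c, is_const in zip(table.feature_columns, constant) if is_const],
    }
    return FeatureTable(data=data, feature_columns=tuple(kept)), params


def _encode_labels(groups: pd.Series, case_label: str) -> np.ndarray:
    """+1 for control-like, -1 for case; orientation fixed by case_label."""
    labels = groups.astype(str).to_numpy()
    present = set(np.unique(labels))
    if case_label not in present:
        raise ValueError(f"case label {case_label!r} not among groups {sorted(present)}")
    return np.where(labels == case_label, -1.0, 1.0)


def _loo_posteriors(
    Z: np.ndarray,
    y: np.ndarray,
    C: float,
    tol: float,
    max_iter: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Decision values and Platt posteriors of held-out conversations."""
    counts = {v: int((y == v).sum()) for v in (-1.0, 1.0)}
    if min(counts.values()) < 2:
        raise ValueError(
            "a leave-one-out fold would lose an entire group "
            f"(group sizes {counts})"
        )
    f = _svm._loo_decision_values(_svm.augment(Z), y, C, tol, max_iter, seed)
    A, B = _svm.fit_platt(f, (y > 0).astype(float))
    posterior = _svm.platt_predict(f, A, B)
    return f, posterior, (A, B)


def loo_classify(
    table: FeatureTable,
    regularization_strength: float = 1.0,
    case_label: str = "case",
    *,
    standardized: bool = False,
    per_fold_standardize: bool = False,
    tol: float = 1e-6,
    max_iter: int = 20000,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-out classification of conversations.

    Each conversation is scored by a classifier trained on all the others;
    pooled cross-validated decision values are Platt-calibrated into
    posterior probabilities of control-group membership (higher = more
    control-like regardless of label encoding).

    By default features are z-scored once over the full table before
    cross-validation (pass ``standardized=True`` if already done);
    ``per_fold_standardize=True`` instead re-estimates the z-scoring inside
    every training fold, which avoids leaking the held-out conversation's
    contribution to the feature moments at the cost of a slower fit.
    """
    work = table if standardized else standardize(table)[0]
    y = _encode_labels(work.data["group"], case_label)
    Z = work.features
    if per_fold_standardize:
        n = Z.shape[0]
        f = np.empty(n)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            mu = Z[mask].mean(axis=0)
            sd = Z[mask].std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            w = _svm.fit_hinge_svm(
                (Z[mask] - mu) / sd, y[mask], C=regularization_strength,
                tol=tol, max_iter=max_iter, seed=seed + i,
            )
            f[i] = w[:-1] @ ((Z[i] - mu) / sd) + w[-1]
        A, B = _svm.fit_platt(f, (y > 0).astype(float))
        posterior = _svm.platt_predict(f, A, B)
    else:
        f, posterior, (A, B) = _loo_posteriors(
            Z, y, regularization_strength, tol, max_iter, seed
        )
    return pd.DataFrame(
        {
            "conversation_id": work.data["conversation_id"].to_numpy(),
            "participant_id": work.data["participant_id"].to_numpy(),
            "decision_value": f,
            "posterior": posterior,
        }
    )


def composite_scores(
    scores: pd.DataFrame,
    roster: pd.DataFrame,
    cutoff: float = 0.5,
    case_label: str = "case",
) -> pd.DataFrame:
    """Average each participant's conversation posteriors into one composite.

    predicted_group is the case label iff composite < cutoff (a composite
    exactly at the cutoff is classified as control — the "lower than 0.5"
    rule).  Rostered participants without conversations are dropped with a
    warning.
    """
    roster = roster.drop_duplicates("participant_id")
    labels = roster["group"].astype(str).unique()
    control_label = [g for g in labels if g != case_label]
    if case_label not in labels or len(control_label) != 1:
        raise ValueError(f"roster must contain the case label {case_label!r} and one other group")
    control_label = control_label[0]
    unrostered = set(scores["participant_id"]) - set(roster["participant_id"])
    if unrostered:
        raise ValueError(f"conversations from unrostered participants: {sorted(unrostered)}")
    agg = scores.groupby("participant_id")["posterior"].agg(["mean", "size"])
    merged = roster.merge(agg, left_on="participant_id", right_index=True, how="left")
    missing = merged["mean"].isna()
    if missing.any():
        warnings.warn(
            "participants with zero conversations excluded: "
            f"{merged.loc[missing, 'participant_id'].tolist()}"
        )
        merged = merged[~missing]
    composite = merged["mean"].to_numpy()
    out = pd.DataFrame(
        {
            "participant_id": merged["participant_id"].to_numpy(),
            "composite": composite,
            "predicted_group": np.where(composite < cutoff, case_label, control_label),
            "true_group": merged["group"].astype(str).to_numpy(),
            "n_conversations": merged["size"].astype(int).to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def evaluate_accuracy(composites: pd.DataFrame) -> float:
    """Fraction of participants whose predicted group matches their true group."""
    if len(composites) == 0:
        raise ValueError("no participants to evaluate")
    return float((composites["predicted_group"] == composites["true_group"]).mean())


@dataclass
class PermutationResult:
    observed_accuracy: float
    p_value: float
    p_value_smoothed: float
    null_accuracies: np.ndarray
    n_permutations: int


def _chain_accuracy(
    Za: np.ndarray,
    y_conv: np.ndarray,
    part_index: np.ndarray,
    part_sign: np.ndarray,
    cutoff: float,
    C: float,
    tol: float,
    max_iter: int,
    seed: int,
) -> float:
    """Accuracy of the full LOO -> Platt -> composite chain for one labeling.

    Za: augmented standardized features; y_conv: +-1 per conversation;
    part_sign: +-1 per participant (+1 = control-like).  Scored against the
    labels the chain was trained on.
    """
    f = _svm._loo_decision_values(Za, y_conv, C, tol, max_iter, seed)
    A, B = _svm._platt_fit(f, (y_conv > 0).astype(float))
    post = _svm.platt_predict(f, A, B)
    n_part = part_sign.shape[0]
    sums = np.bincount(part_index, weights=post, minlength=n_part)
    counts = np.bincount(part_index, minlength=n_part)
    comp = sums / counts
    predicted_control = comp >= cutoff
    return float((predicted_control == (part_sign > 0)).mean())


def permutation_test(
    table: FeatureTable,
    n_permutations: int = 1000,
    seed: int = 0,
    regularization_strength: float = 1.0,
    cutoff: float = 0.5,
    case_label: str = "case",
    *,
    tol: float = 1e-4,
    max_iter: int = 2000,
    resume_null: "np.ndarray | list[float] | None" = None,
) -> PermutationResult:
    """Participant-level label-permutation test of composite accuracy.

    Every permutation relabels whole participants (all of a participant's
    conversations move together, group sizes preserved), reruns the full
    LOO -> calibration -> composite chain against the permuted labels, and
    records the resulting accuracy.  The primary p is the proportion of
    null accuracies strictly greater than the observed one; the add-one
    smoothed estimator (#{null >= observed} + 1) / (n + 1), which can never
    be exactly zero, is reported alongside.
    """
    work = standardize(table)[0]
    Za = _svm.augment(work.features)
    pids, part_index = np.unique(work.data["participant_id"].to_numpy(), return_inverse=True)
    roster = work.roster().set_index("participant_id")["group"].astype(str)
    part_sign = np.where(roster.loc[pids].to_numpy() == case_label, -1.0, 1.0)
    y_conv = part_sign[part_index]
    C = regularization_strength
    base_seed = substream_seed(seed, "permutation-test")
    observed = _chain_accuracy(
        Za, y_conv, part_index, part_sign, cutoff, C, tol, max_iter, base_seed
    )
    rng = substream(seed, "permutation-test")
    null = np.empty(n_permutations)
    done = 0
    if resume_null is not None:
        done = min(len(resume_null), n_permutations)
        null[:done] = np.asarray(resume_null, dtype=float)[:done]
    for b in range(n_permutations):
        perm_sign = rng.permutation(part_sign)
        if b < done:
            continue  # checkpointed permutation: redraw to keep the stream aligned
        null[b] = _chain_accuracy(
            Za, perm_sign[part_index], part_index, perm_sign, cutoff, C, tol,
            max_iter, base_seed + 1 + b,
        )
    p_strict = float((null > observed).sum()) / n_permutations
    p_smooth = (float((null >= observed).sum()) + 1.0) / (n_permutations + 1.0)
    logger.info(
        "permutation test: observed accuracy %.3f, p=%.4g (smoothed %.4g) over %d permutations",
        observed, p_strict, p_smooth, n_permutations,
    )
    return PermutationResult(observed, p_strict, p_smooth, null, n_permutations)


def _spearman_exact_p(a: np.ndarray, b: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho at n <= 9."""
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    n = len(ra)
    perms = np.array(list(_iter_permutations(range(n))))
    ra_perm = ra[perms]  # (n!, n)
    rb_c = rb - rb.mean()
    ra_c = ra_perm - ra_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((ra_c**2).sum(axis=1) * (rb_c**2).sum())
    rhos = (ra_c @ rb_c) / denom
    return float((np.abs(rhos) >= abs(rho_obs) - 1e-12).mean())


def validate_severity(
    composites: pd.DataFrame,
    severity: pd.DataFrame,
    case_label: str = "case",
    exact_max_n: int = 9,
) -> tuple[float, float]:
    """Spearman correlation of case-group composites with severity scores.

    Ties get average ranks.  The two-sided p uses the large-sample t
    approximation, replaced by exact permutation enumeration for n <= 9.
    """
    case = composites[composites["true_group"] == case_label]
    merged = case.merge(severity[["participant_id", "severity"]], on="participant_id")
    merged = merged.dropna(subset=["severity"])
    if len(merged) < 4:
        raise ValueError(f"need >= 4 severity-composite pairs, found {len(merged)}")
    x = merged["composite"].to_numpy(dtype=float)
    s = merged["severity"].to_numpy(dtype=float)
    rho, p = stats.spearmanr(x, s)
    if len(merged) <= exact_max_n:
        p = _spearman_exact_p(x, s, rho)
    return float(rho), float(p)


def roc_analysis(
    composites: pd.DataFrame,
    case_label: str = "case",
) -> tuple[pd.DataFrame, float]:
    """ROC of the composite as a continuous score (positive = control).

    AUC by trapezoidal rule; equals the probability that a random control
    participant outscores a random case participant, ties counting 1/2.
    """
    from sklearn import metrics

    truth = (composites["true_group"] != case_label).astype(int).to_numpy()
    score = composites["composite"].to_numpy(dtype=float)
    if truth.min() == truth.max():
        raise ValueError("ROC needs both groups present")
    fpr, tpr, thr = metrics.roc_curve(truth, score)
    auc = float(metrics.roc_auc_score(truth, score))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return points, auc


@dataclass
class ClassifierEvaluation:
    accuracy: float
    n_correct: int
    n_total: int
    permutation_p: float
    permutation_p_smoothed: float
    null_accuracies: np.ndarray
    roc_auc: float
    spearman_rho: Optional[float] = None
    spearman_p: Optional[float] = None
    composites: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)
    scores: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)


def evaluate_classifier(
    table: FeatureTable,
    config: RunConfig,
    severity: pd.DataFrame | None = None,
) -> ClassifierEvaluation:
    """Run the full phenotype chain and collect the evaluation surface."""
    scores = loo_classify(
        table,
        regularization_strength=config.regularization_strength,
        case_label=config.case_label,
        seed=substream_seed(config.seed, "loo-classify"),
    )
    comps = composite_scores(
        scores, table.roster(), cutoff=config.composite_cutoff, case_label=config.case_label
    )
    acc = evaluate_accuracy(comps)
    perm = permutation_test(
        table,
        n_permutations=config.n_permutations,
        seed=config.seed,
        regularization_strength=config.regularization_strength,
        cutoff=config.composite_cutoff,
        case_label=config.case_label,
    )
    _, auc = roc_analysis(comps, case_label=config.case_label)
    rho = p_rho = None
    if severity is not None:
        rho, p_rho = validate_severity(comps, severity, case_label=config.case_label)
    n_correct = int((comps["predicted_group"] == comps["true_group"]).sum())
    return ClassifierEvaluation(
        accuracy=acc,
        n_correct=n_correct,
        n_total=len(comps),
        permutation_p=perm.p_value,
        permutation_p_smoothed=perm.p_value_smoothed,
        null_accuracies=perm.null_accuracies,
        roc_auc=auc,
        spearman_rho=rho,
        spearman_p=p_rho,
        composites=comps,
        scores=scores,
    )


def control_classifier(
    table_partner_speech: FeatureTable,
    config: RunConfig,
    participant_table: FeatureTable | None = None,
    severity: pd.DataFrame | None = None,
) -> ClassifierEvaluation:
    """Negative-control chain on the conversation partner's speech features.

    The partner table must cover exactly the conversations of the
    participant table (same conversation roster); the identical pipeline is
    then applied.  Group labels describe the *participant* in the
    conversation, so chance-level accuracy here indicates the partner's
    language carries no group signal.
    """
    if participant_table is not None:
        ours = set(table_partner_speech.data["conversation_id"].astype(str))
        theirs = set(participant_table.data["conversation_id"].astype(str))
        if ours != theirs:
            raise ValueError(
                "partner table conversation roster differs from participant table "
                f"(missing {sorted(theirs - ours)}, extra {sorted(ours - theirs)})"
            )
    return evaluate_classifier(table_partner_speech, config, severity=severity)
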