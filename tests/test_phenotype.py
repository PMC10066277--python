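"""Phenotype-chain tests: standardization, LOO scores, composites, validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from convoconn import phenotype
from convoconn.core import FeatureTable

from conftest import make_feature_table


def test_standardize_zero_mean_unit_sd(tiny_table):
    std, params = phenotype.standardize(tiny_table)
    Z = std.features
    assert np.abs(Z.mean(axis=0)).max() < 1e-10
    assert np.abs(Z.std(axis=0, ddof=1) - 1.0).max() < 1e-10
    assert params["columns"] == list(std.feature_columns)


def test_standardize_drops_constant_columns(tiny_table):
    data = tiny_table.data.copy()
    data["const"] = 3.14
    table = FeatureTable(data=data, feature_columns=tiny_table.feature_columns + ("const",))
    with pytest.warns(UserWarning, match="constant"):
        std, params = phenotype.standardize(table)
    assert "const" not in std.feature_columns
    assert params["dropped"] == ["const"]


def test_standardize_all_constant_errors(tiny_table):
    data = tiny_table.data.copy()
    for c in tiny_table.feature_columns:
        data[c] = 1.0
    table = FeatureTable(data=data, feature_columns=tiny_table.feature_columns)
    with pytest.raises(ValueError, match="constant"):
        phenotype.standardize(table)


def test_loo_separable_clusters_classified_perfectly(separable_table):
    scores = phenotype.loo_classify(separable_table, case_label="case", seed=0)
    merged = scores.merge(
        separable_table.data[["conversation_id", "group"]], on="conversation_id"
    )
    case_post = merged.loc[merged["group"] == "case", "posterior"]
    ctrl_post = merged.loc[merged["group"] == "control", "posterior"]
    assert (case_post < 0.5).all()
    assert (ctrl_post > 0.5).all()
    comps = phenotype.composite_scores(scores, separable_table.roster())
    assert phenotype.evaluate_accuracy(comps) == 1.0


def test_loo_decision_values_invariant_to_feature_order(tiny_table):
    scores = phenotype.loo_classify(tiny_table, case_label="case", seed=5)
    reordered = FeatureTable(
        data=tiny_table.data,
        feature_columns=tuple(reversed(tiny_table.feature_columns)),
    )
    scores2 = phenotype.loo_classify(reordered, case_label="case", seed=5)
    np.testing.assert_allclose(
        scores["decision_value"], scores2["decision_value"], atol=1e-5
    )


def test_loo_invariant_to_added_constant_feature(tiny_table):
    scores = phenotype.loo_classify(tiny_table, case_label="case", seed=5)
    data = tiny_table.data.copy()
    data["const"] = 7.0
    augmented = FeatureTable(data=data, feature_columns=tiny_table.feature_columns + ("const",))
    with pytest.warns(UserWarning):
        scores2 = phenotype.loo_classify(augmented, case_label="case", seed=5)
    np.testing.assert_allclose(
        scores["decision_value"], scores2["decision_value"], atol=1e-5
    )


def test_loo_fold_losing_a_group_errors():
    table = make_feature_table(n_per_group=1, n_conversations=1, n_features=2)
    with pytest.raises(ValueError, match="entire group"):
        phenotype.loo_classify(table, case_label="case")


def test_composite_mean_and_cutoff_rule():
    scores = pd.DataFrame(
        {
            "conversation_id": ["a1", "a2", "a3", "b1", "b2", "b3", "c1"],
            "participant_id": ["a", "a", "a", "b", "b", "b", "c"],
            "decision_value": np.zeros(7),
            "posterior": [0.2, 0.4, 0.6, 0.5, 0.5, 0.5, 0.9],
        }
    )
    roster = pd.DataFrame(
        {"participant_id": ["a", "b", "c"], "group": ["case", "case", "control"]}
    )
    comps = phenotype.composite_scores(scores, roster).set_index("participant_id")
    assert comps.loc["a", "composite"] == pytest.approx(0.4)
    assert comps.loc["a", "predicted_group"] == "case"
    # composite exactly at the cutoff is control ("lower than 0.5" rule)
    assert comps.loc["b", "composite"] == pytest.approx(0.5)
    assert comps.loc["b", "predicted_group"] == "control"
    # single conversation: composite equals that posterior
    assert comps.loc["c", "composite"] == pytest.approx(0.9)


def test_composite_warns_on_participant_without_conversations():
    scores = pd.DataFrame(
        {
            "conversation_id": ["a1", "b1", "b2", "c1"],
            "participant_id": ["a", "b", "b", "c"],
            "decision_value": np.zeros(4),
            "posterior": [0.3, 0.6, 0.8, 0.2],
        }
    )
    roster = pd.DataFrame(
        {"participant_id": ["a", "b", "c", "d"], "group": ["case", "control", "case", "control"]}
    )
    with pytest.warns(UserWarning, match="zero conversations"):
        comps = phenotype.composite_scores(scores, roster)
    assert set(comps["participant_id"]) == {"a", "b", "c"}


def test_evaluate_accuracy_cohort_fraction():
    """29 correct of 39 participants is the printed-style 74% regime."""
    comps = pd.DataFrame(
        {
            "participant_id": [f"p{i}" for i in range(39)],
            "composite": np.linspace(0.1, 0.9, 39),
            "predicted_group": ["case"] * 29 + ["control"] * 10,
            "true_group": ["case"] * 29 + ["case"] * 10,
        }
    )
    assert phenotype.evaluate_accuracy(comps) == pytest.approx(29 / 39)
    all_right = comps.assign(predicted_group=comps["true_group"])
    assert phenotype.evaluate_accuracy(all_right) == 1.0
    flipped = comps.assign(predicted_group="control", true_group="case")
    assert phenotype.evaluate_accuracy(flipped) == 0.0


def test_permutation_null_preserves_group_sizes(tiny_table):
    res = phenotype.permutation_test(tiny_table, n_permutations=5, seed=0)
    assert len(res.null_accuracies) == 5
    # accuracies are multiples of 1/n_participants: a relabeling keeps sizes
    n_part = tiny_table.data["participant_id"].nunique()
    np.testing.assert_allclose(
        res.null_accuracies * n_part, np.round(res.null_accuracies * n_part), atol=1e-12
    )


def test_permutation_p_boundary_definitions():
    """Observed beating every null gives p=0 (strict) and 1/(n+1) smoothed."""
    table = make_feature_table(n_per_group=4, n_conversations=2, n_features=3,
                               separation=10.0, seed=3)
    res = phenotype.permutation_test(table, n_permutations=30, seed=1)
    assert res.observed_accuracy == 1.0
    if (res.null_accuracies < 1.0).all():
        assert res.p_value == 0.0
        n_ties = int((res.null_accuracies >= 1.0).sum())
        assert res.p_value_smoothed == pytest.approx((n_ties + 1) / 31)


def test_spearman_hand_worked_tie_example():
    """5 pairs with one tie against the tie-corrected value worked by hand.

    severity ranks (1, 2, 3.5, 3.5, 5) against composite ranks (1..5)
    give rho = -sqrt(9.5/10).
    """
    comps = pd.DataFrame(
        {
            "participant_id": list("abcde"),
            "composite": [0.1, 0.2, 0.3, 0.4, 0.5],
            "predicted_group": ["case"] * 5,
            "true_group": ["case"] * 5,
        }
    )
    severity = pd.DataFrame({"participant_id": list("abcde"), "severity": [10, 9, 9, 8, 7]})
    rho, p = phenotype.validate_severity(comps, severity)
    assert rho == pytest.approx(-np.sqrt(9.5 / 10.0), abs=1e-12)
    # exact enumeration p at n=5 must match a direct scipy permutation test
    ref = stats.spearmanr([0.1, 0.2, 0.3, 0.4, 0.5], [10, 9, 9, 8, 7])
    assert rho == pytest.approx(ref.statistic, abs=1e-12)


def test_spearman_perfect_monotone_and_invariance():
    comps = pd.DataFrame(
        {
            "participant_id": list("abcdef"),
            "composite": [0.1, 0.25, 0.4, 0.55, 0.7, 0.85],
            "predicted_group": ["case"] * 6,
            "true_group": ["case"] * 6,
        }
    )
    severity = pd.DataFrame({"participant_id": list("abcdef"), "severity": [14, 13, 12, 10, 9, 7]})
    rho, _ = phenotype.validate_severity(comps, severity)
    assert rho == pytest.approx(-1.0)
    # monotone relabeling of severity leaves rho unchanged
    severity2 = severity.assign(severity=severity["severity"] ** 3 + 5)
    rho2, _ = phenotype.validate_severity(comps, severity2)
    assert rho2 == pytest.approx(rho, abs=1e-12)


def test_validate_severity_needs_four_pairs():
    comps = pd.DataFrame(
        {
            "participant_id": ["a", "b", "c"],
            "composite": [0.1, 0.2, 0.3],
            "predicted_group": ["case"] * 3,
            "true_group": ["case"] * 3,
        }
    )
    severity = pd.DataFrame({"participant_id": ["a", "b", "c"], "severity": [9, 8, 7]})
    with pytest.raises(ValueError, match=">= 4"):
        phenotype.validate_severity(comps, severity)


def _comps_from(case_scores, control_scores):
    n1, n2 = len(case_scores), len(control_scores)
    return pd.DataFrame(
        {
            "participant_id": [f"p{i}" for i in range(n1 + n2)],
            "composite": list(case_scores) + list(control_scores),
            "predicted_group": ["case"] * (n1 + n2),
            "true_group": ["case"] * n1 + ["control"] * n2,
        }
    )


def test_roc_auc_matches_pair_counting_oracle():
    """AUC equals exhaustive correct-ordering pair counting, ties as 1/2."""
    comps = _comps_from([0.2, 0.3, 0.4], [0.4, 0.6, 0.7])
    _, auc = phenotype.roc_analysis(comps)
    case, ctrl = [0.2, 0.3, 0.4], [0.4, 0.6, 0.7]
    wins = sum(
        1.0 if c > a else (0.5 if c == a else 0.0) for a in case for c in ctrl
    )
    assert auc == pytest.approx(wins / 9.0)


def test_roc_degenerate_cases():
    _, auc = phenotype.roc_analysis(_comps_from([0.1, 0.2], [0.8, 0.9]))
    assert auc == 1.0
    _, auc = phenotype.roc_analysis(_comps_from([0.3, 0.5], [0.3, 0.5]))
    assert auc == pytest.approx(0.5)


def test_control_classifier_identity_and_roster_mismatch(separable_table):
    from convoconn.config import RunConfig

    cfg = RunConfig(seed=0, n_permutations=5)
    ours = phenotype.evaluate_classifier(separable_table, cfg)
    # identical features reproduce the participant-classifier results
    copied = phenotype.control_classifier(
        separable_table, cfg, participant_table=separable_table
    )
    assert copied.accuracy == ours.accuracy
    np.testing.assert_allclose(
        copied.composites["composite"], ours.composites["composite"]
    )
    # missing conversation in the partner table is a roster mismatch
    short = separable_table.with_data(separable_table.data.iloc[1:])
    with pytest.raises(ValueError, match="roster"):
        phenotype.control_classifier(short, cfg, participant_table=separable_table)


def test_composite_orientation_invariant_to_label_names(separable_table):
    """Relabeling groups (with case_label tracking) keeps score orientation."""
    renamed = separable_table.data.replace({"group": {"case": "grpX", "control": "grpY"}})
    table2 = FeatureTable(data=renamed, feature_columns=separable_table.feature_columns)
    s1 = phenotype.loo_classify(separable_table, case_label="case", seed=4)
    s2 = phenotype.loo_classify(table2, case_label="grpX", seed=4)
    np.testing.assert_allclose(s1["posterior"], s2["posterior"], atol=1e-12)
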