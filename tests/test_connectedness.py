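"""Connectedness maps, mixed-model contrast, clustering and thresholds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import sparse, stats

from convoconn import connectedness as cn
from convoconn.core import ConnectednessMap, ScanTimeSeries, maps_to_wide


def _scan(data, scan_id="s1", participant_id="p1", hemis=None, **kw):
    n = data.shape[0]
    nodes = pd.DataFrame(
        {
            "node_id": [f"n{i}" for i in range(n)],
            "hemisphere": hemis or ["L"] * n,
            "x": [0.0] * n,
            "y": [float(i) for i in range(n)],
            "z": [0.0] * n,
        }
    )
    return ScanTimeSeries(scan_id=scan_id, participant_id=participant_id,
                          data=data, nodes=nodes, age=20.0, motion=0.1, **kw)


def brute_force_connectedness(data):
    """Off-diagonal row means of the per-pair Pearson correlation matrix."""
    n = data.shape[0]
    out = np.empty(n)
    for i in range(n):
        rs = [stats.pearsonr(data[i], data[j]).statistic for j in range(n) if j != i]
        out[i] = np.mean(rs)
    return out


def test_two_nodes_share_their_correlation():
    rng = np.random.default_rng(0)
    data = rng.normal(size=(2, 60))
    m = cn.compute_connectedness(_scan(data))
    r12 = stats.pearsonr(data[0], data[1]).statistic
    np.testing.assert_allclose(m.values, [r12, r12], atol=1e-12)


def test_connectedness_matches_brute_force_matrix_oracle():
    rng = np.random.default_rng(1)
    data = rng.normal(size=(6, 80))
    data[1] = data[0] * 2.0 + 1.0  # exact copy up to affine scale
    m = cn.compute_connectedness(_scan(data))
    np.testing.assert_allclose(m.values, brute_force_connectedness(data), atol=1e-12)


def test_connectedness_fisher_z_mode():
    rng = np.random.default_rng(2)
    data = rng.normal(size=(4, 50))
    m = cn.compute_connectedness(_scan(data), fisher_z=True)
    r = np.corrcoef(data)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    np.fill_diagonal(z, 0.0)
    np.testing.assert_allclose(m.values, z.sum(axis=1) / 3.0, atol=1e-12)
    assert m.scale == "z"


@given(st.floats(0.1, 50.0), st.floats(-5.0, 5.0))
def test_connectedness_invariant_to_affine_node_rescaling(scale, shift):
    rng = np.random.default_rng(4)
    data = rng.normal(size=(5, 40))
    base = cn.compute_connectedness(_scan(data)).values
    data2 = data.copy()
    data2[2] = data2[2] * scale + shift
    rescaled = cn.compute_connectedness(_scan(data2)).values
    np.testing.assert_allclose(base, rescaled, atol=1e-10)


def test_constant_node_flagged_not_fatal():
    rng = np.random.default_rng(5)
    data = rng.normal(size=(4, 30))
    data[2] = 1.5
    m = cn.compute_connectedness(_scan(data))
    assert np.isnan(m.values[2])
    others = np.delete(data, 2, axis=0)
    np.testing.assert_allclose(
        np.delete(m.values, 2), brute_force_connectedness(others), atol=1e-12
    )


def test_too_few_timepoints_errors():
    with pytest.raises(ValueError, match="timepoints"):
        cn.compute_connectedness(_scan(np.zeros((3, 2)) + np.arange(2)))


def _random_maps(n_participants=20, n_nodes=8, scans_per=1, seed=0, effect=None):
    rng = np.random.default_rng(seed)
    maps, cov_rows = [], []
    for p in range(n_participants):
        group = "case" if p < n_participants // 2 else "control"
        age = rng.uniform(15, 30)
        motion = rng.uniform(0.05, 0.2)
        offset = rng.normal() * 0.05  # participant-level random intercept
        for s in range(scans_per):
            vals = rng.normal(size=n_nodes) * 0.1 + offset
            if effect is not None and group == "case":
                vals += effect
            sid = f"p{p}_s{s}"
            maps.append(ConnectednessMap(scan_id=sid, participant_id=f"p{p}",
                                         node_ids=tuple(f"n{i}" for i in range(n_nodes)),
                                         values=np.clip(vals, -1, 1)))
            cov_rows.append({"scan_id": sid, "participant_id": f"p{p}", "group": group,
                             "age": age, "motion": motion})
    return maps, pd.DataFrame(cov_rows)


def test_single_scan_mixed_model_equals_ols_closed_form():
    """With one scan per participant the mixed fit collapses to OLS."""
    maps, cov = _random_maps(n_participants=16, n_nodes=5, scans_per=1, seed=3)
    lme = cn.fit_group_contrast(maps, cov, engine="mixedlm")
    ols = cn.fit_group_contrast(maps, cov, engine="ols")
    np.testing.assert_allclose(lme["estimate"], ols["estimate"], atol=1e-8)


def test_contrast_reduces_to_group_mean_difference():
    """Zero covariates and balanced groups give the difference of means."""
    maps, cov = _random_maps(n_participants=12, n_nodes=4, scans_per=2, seed=6)
    cov["age"] = 0.0
    cov["motion"] = 0.0
    # drop covariate columns from the design by making them constant-zero:
    # the group estimate must equal the difference of group participant means
    wide = maps_to_wide(maps)
    merged = wide.merge(cov[["scan_id", "group"]], on="scan_id")
    pm = merged.groupby(["participant_id"]).agg(
        {**{f"n{i}": "mean" for i in range(4)}, "group": "first"})
    diff = pm[pm.group == "case"].mean(numeric_only=True) - pm[pm.group == "control"].mean(numeric_only=True)
    est = cn.fit_group_contrast(maps, cov, engine="ols")["estimate"]
    np.testing.assert_allclose(est, diff.to_numpy(), atol=1e-8)


def test_mixed_engine_matches_statsmodels_reference():
    """The profiled-REML solver agrees with statsmodels MixedLM per node."""
    maps, cov = _random_maps(n_participants=14, n_nodes=4, scans_per=3, seed=21,
                             effect=np.array([0.2, 0.0, 0.0, 0.1]))
    fast = cn.fit_group_contrast(maps, cov, engine="mixedlm")
    ref = cn.fit_group_contrast(maps, cov, engine="statsmodels")
    assert not fast["fallback_ols"].any() and not ref["fallback_ols"].any()
    np.testing.assert_allclose(fast["estimate"], ref["estimate"], atol=1e-5)
    np.testing.assert_allclose(fast["t"], ref["t"], rtol=2e-2)


def test_contrast_recovers_planted_group_difference():
    effect = np.array([0.3, 0.3, 0.0, 0.0, 0.0])
    maps, cov = _random_maps(n_participants=30, n_nodes=5, scans_per=2, seed=7,
                             effect=effect)
    res = cn.fit_group_contrast(maps, cov, engine="mixedlm")
    assert res["estimate"].iloc[0] == pytest.approx(0.3, abs=0.08)
    assert res["estimate"].iloc[4] == pytest.approx(0.0, abs=0.08)
    assert (res.loc[:1, "p_one_sided"] < 0.001).all()


def _chain_adjacency(n):
    rows = list(range(n - 1))
    cols = list(range(1, n))
    data = np.ones(n - 1)
    a = sparse.coo_matrix((data, (rows, cols)), shape=(n, n))
    return (a + a.T).tocsr()


def test_find_clusters_chain_split():
    mask = np.array([1, 1, 0, 1, 1], dtype=bool)
    clusters = cn.find_clusters(mask, _chain_adjacency(5))
    assert sorted(sorted(c.tolist()) for c in clusters) == [[0, 1], [3, 4]]
    assert cn.find_clusters(np.zeros(5, bool), _chain_adjacency(5)) == []


def test_find_clusters_matches_networkx_oracle():
    import networkx as nx

    rng = np.random.default_rng(8)
    n = 25
    g = nx.gnp_random_graph(n, 0.12, seed=4)
    adj = sparse.csr_matrix(nx.to_scipy_sparse_array(g))
    mask = rng.random(n) < 0.6
    ours = {frozenset(c.tolist()) for c in cn.find_clusters(mask, adj)}
    sub = g.subgraph(np.flatnonzero(mask))
    theirs = {frozenset(c) for c in nx.connected_components(sub)}
    assert ours == theirs


def test_extent_table_validates_monotonicity():
    tab = cn.extent_table([0.005, 0.001], [51, 22])
    assert list(tab["k"]) == [51, 22]
    with pytest.raises(ValueError, match="non-increasing"):
        cn.extent_table([0.005, 0.001], [10, 22])


def test_calibration_no_adjacency_gives_k1():
    """Isolated nodes: singleton clusters suffice at a modest threshold."""
    maps, cov = _random_maps(n_participants=16, n_nodes=6, seed=9)
    none_adj = sparse.csr_matrix((6, 6))
    tab = cn.calibrate_cluster_extent(maps, cov, none_adj, [0.005], n_iter=200, seed=0)
    assert list(tab["k"]) == [1]


def test_calibration_alpha_one_fully_connected_gives_node_count():
    maps, cov = _random_maps(n_participants=12, n_nodes=6, seed=10)
    full = sparse.csr_matrix(np.ones((6, 6)) - np.eye(6))
    tab = cn.calibrate_cluster_extent(maps, cov, full, [0.9999999], n_iter=100, seed=0)
    assert list(tab["k"]) == [6]


def test_calibration_matches_oversampled_oracle():
    """k on a 20-node chain at alpha 0.05 agrees with a 10x-iteration run."""
    maps, cov = _random_maps(n_participants=24, n_nodes=20, seed=11)
    adj = _chain_adjacency(20)
    k1 = cn.calibrate_cluster_extent(maps, cov, adj, [0.05], n_iter=400, seed=1)["k"][0]
    k2 = cn.calibrate_cluster_extent(maps, cov, adj, [0.05], n_iter=4000, seed=2)["k"][0]
    assert abs(int(k1) - int(k2)) <= 1


def test_calibration_rejects_insufficient_iterations():
    maps, cov = _random_maps(n_participants=10, n_nodes=4, seed=12)
    with pytest.raises(ValueError, match="too small"):
        cn.calibrate_cluster_extent(maps, cov, _chain_adjacency(4), [0.05], n_iter=20)


def test_voxelwise_masks_nested_across_thresholds():
    maps, cov = _random_maps(n_participants=20, n_nodes=10, seed=13,
                             effect=np.linspace(0, 0.3, 10))
    contrast = cn.fit_group_contrast(maps, cov, engine="ols")
    p = contrast["p_one_sided"].to_numpy()
    thresholds = [0.05, 0.01, 0.001]
    for a_loose, a_tight in zip(thresholds, thresholds[1:]):
        assert np.all((p < a_tight) <= (p < a_loose))


def test_robustness_map_extent_rule_and_max_index():
    # 6 nodes on a chain; nodes 0-2 strongly significant, node 4 significant
    # alone (cluster of 1 below every k>=2), node 5 null
    contrast = pd.DataFrame(
        {
            "node_id": [f"n{i}" for i in range(6)],
            "estimate": [0.5, 0.5, 0.5, 0.0, 0.5, 0.0],
            "t": [9.0, 9.0, 9.0, 0.0, 9.0, 0.0],
            "df": 20,
            "p": [1e-9, 1e-9, 1e-9, 0.9, 1e-9, 0.9],
            "p_one_sided": [5e-10, 5e-10, 5e-10, 0.55, 5e-10, 0.55],
            "fallback_ols": False,
        }
    )
    thresholds = [0.005, 0.001, 0.0005, 0.0001, 0.00005, 0.00001]
    ext = cn.extent_table(thresholds, [2, 2, 2, 2, 2, 2])
    robust = cn.build_robustness_map(contrast, thresholds, ext, _chain_adjacency(6))
    assert list(robust.max_index[:3]) == [6, 6, 6]
    assert robust.max_index[4] == 0  # significant node in an undersized cluster
    assert robust.max_index[5] == 0
    rois = cn.select_rois(robust, _chain_adjacency(6), min_size=3)
    assert len(rois) == 1
    assert set(rois["roi_1"]) == {"n0", "n1", "n2"}
    rois_all = cn.select_rois(robust, _chain_adjacency(6), min_size=1)
    assert len(rois_all) == 1  # node 4 never survives, so still one cluster
    # missing threshold in the extent table is a validation error
    with pytest.raises(ValueError, match="missing"):
        cn.build_robustness_map(contrast, thresholds, cn.extent_table([0.005], [2]),
                                _chain_adjacency(6))


def test_select_rois_empty_when_nothing_survives():
    contrast = pd.DataFrame(
        {
            "node_id": ["n0", "n1"],
            "estimate": [0.0, 0.0],
            "t": [0.1, 0.1],
            "df": 10,
            "p": [0.9, 0.9],
            "p_one_sided": [0.45, 0.45],
            "fallback_ols": False,
        }
    )
    ext = cn.extent_table([0.005], [1])
    robust = cn.build_robustness_map(contrast, [0.005], ext, _chain_adjacency(2))
    assert len(cn.select_rois(robust, _chain_adjacency(2), min_size=1)) == 0


def test_maps_scale_mixing_rejected():
    rng = np.random.default_rng(14)
    data = rng.normal(size=(3, 40))
    m1 = cn.compute_connectedness(_scan(data, scan_id="a"))
    m2 = cn.compute_connectedness(_scan(data, scan_id="b"), fisher_z=True)
    with pytest.raises(ValueError, match="mix"):
        maps_to_wide([m1, m2])
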