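import numpy as np
import pandas as pd
import pytest

import sabnet as sn
from sabnet.mom import GroupData, _impute_adjacency, _impute_behavior
from sabnet.panel import MISSING

E = sn.EffectSpec


def _two_wave_panel(adj0, adj1, z0, z1, ids=None):
    adj = np.stack([adj0, adj1]).astype(np.int8)
    n = adj0.shape[0]
    ids = ids or [f"a{k}" for k in range(n)]
    panel = sn.NetworkPanel(["w1", "w2"], adj, ids)
    beh = sn.BehaviorPanel("alcohol", np.stack([z0, z1]).astype(float))
    return panel, beh


def _fixture_a_adj():
    x = np.zeros((4, 4), dtype=np.int8)
    for i, j in ((0, 1), (1, 0), (1, 2), (2, 3), (0, 2)):
        x[i, j] = 1
    return x


def test_identical_waves_zero_rate_targets():
    x = _fixture_a_adj()
    z = np.array([1.0, 2, 3, 3])
    panel, beh = _two_wave_panel(x, x, z, z)
    model = sn.ModelSpec("alcohol", [E("outdegree"),
                                     E("linear", target="behavior")])
    t = sn.observed_targets(panel, beh, model)
    assert t.values[0] == 0  # network changes
    assert t.values[1] == 0  # behavior changes


def test_outdegree_target_is_total_tie_count():
    x1 = _fixture_a_adj()
    x0 = np.zeros_like(x1)
    z = np.array([1.0, 2, 3, 3])
    panel, beh = _two_wave_panel(x0, x1, z, z)
    model = sn.ModelSpec("alcohol", [E("outdegree"),
                                     E("linear", target="behavior")])
    t = sn.observed_targets(panel, beh, model)
    labels = dict(zip(t.labels, t.values))
    assert labels["net:outdegree"] == 5.0
    assert labels["rate:net:group:p1"] == 5.0


def test_masked_actor_targets_match_reduced_recomputation():
    x1 = _fixture_a_adj()
    x0 = np.zeros_like(x1)
    z = np.array([1.0, 2, 3, 3])
    x1_missing = x1.copy()
    x1_missing[1, :] = MISSING  # actor 2 nonrespondent at wave 2
    np.fill_diagonal(x1_missing, 0)
    panel, beh = _two_wave_panel(x0, x1_missing, z, z)
    model = sn.ModelSpec("alcohol", [E("outdegree"),
                                     E("linear", target="behavior")],
                         center_behavior=False)
    t = dict(zip(*[sn.observed_targets(panel, beh, model).labels,
                   sn.observed_targets(panel, beh, model).values]))
    # recompute on the reduced network with actor 2's row removed
    x_red = x1.copy()
    x_red[1, :] = 0
    expected = x_red.sum()
    assert t["net:outdegree"] == expected


def test_all_missing_wave_errors():
    adj = np.full((2, 4, 4), MISSING, dtype=np.int8)
    adj[0] = _fixture_a_adj()
    for i in range(4):
        adj[1, i, i] = 0
    panel = sn.NetworkPanel(["w1", "w2"], adj, list("abcd"))
    beh = sn.BehaviorPanel("alcohol", np.full((2, 4), 2.0))
    with pytest.raises(ValueError, match="w2"):
        GroupData(panel, beh)


def test_model_without_free_effects_errors():
    x = _fixture_a_adj()
    z = np.array([1.0, 2, 3, 3])
    panel, beh = _two_wave_panel(np.zeros_like(x), x, z, z)
    model = sn.ModelSpec("alcohol", [E("outdegree", fixed=True)])
    with pytest.raises(ValueError, match="free effects"):
        sn.observed_targets(panel, beh, model)


def test_imputation_locf_and_backfill():
    adj = np.zeros((3, 3, 3), dtype=np.int8)
    adj[0, 0, 1] = 1
    adj[1, :, :] = MISSING
    for i in range(3):
        adj[1, i, i] = 0
    adj[2, 0, 2] = 1
    panel = sn.NetworkPanel(["w1", "w2", "w3"], adj, list("abc"))
    imp = _impute_adjacency(panel)
    assert imp[1, 0, 1] == 1  # carried forward
    assert imp[2, 0, 1] == 0  # wave 3 observed 0 overrides

    beh = sn.BehaviorPanel("alcohol", np.array(
        [[np.nan, 2.0, np.nan], [4.0, np.nan, np.nan],
         [5.0, 3.0, np.nan]]))
    z = _impute_behavior(beh)
    assert z[0, 0] == 4.0  # leading missing backfilled
    assert z[1, 1] == 2.0  # carried forward
    assert not np.isnan(z).any()  # never-observed actor gets fallback


def test_target_statistics_validation():
    with pytest.raises(ValueError):
        sn.TargetStatistics(["a"], np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        sn.TargetStatistics(["a"], np.array([np.inf]))


def test_fit_recovers_null_parameters():
    """Data generated with all effect parameters 0: estimates of
    outdegree (at its null -1... none) and reciprocity near truth."""
    n = 30
    rng = np.random.default_rng(8)
    x0 = (rng.random((n, n)) < 0.12).astype(np.int8)
    np.fill_diagonal(x0, 0)
    z0 = rng.integers(1, 7, n).astype(float)
    truth = sn.ModelSpec("alcohol", [
        E("outdegree", parameter=-2.0),
        E("reciprocity", parameter=0.0),
        E("linear", target="behavior", parameter=0.0),
    ])
    start = sn.StateView(x0, z0, z_name="alcohol",
                         means={"alcohol": float(z0.mean())})
    panel, beh = sn.forward_simulate_panel(
        start, sn.RateSchedule([3.0], [1.0]), truth, 2, seed=2)
    model = truth.with_parameters([0.0, 0.0, 0.0])
    opts = sn.FitOptions(seed=3, n_phase1=15, n_phase2_iter=20,
                         phase3_iterations=120, max_reruns=1)
    res = sn.fit(panel, beh, model, options=opts)
    b, se = res.get("net:reciprocity")
    assert abs(b - 0.0) < 3 * se
    b, se = res.get("net:outdegree")
    assert abs(b - (-2.0)) < 3 * se
    assert (res.se >= 0).all()
    assert res.rates.shape == (2,)


def test_multigroup_needs_two_groups():
    with pytest.raises(ValueError):
        sn.MultigroupSpec([], sn.ModelSpec("alcohol", [E("outdegree")]))


def test_no_observed_change_errors():
    x = _fixture_a_adj()
    z = np.array([1.0, 2, 3, 3])
    panel, beh = _two_wave_panel(x, x, z, z)
    model = sn.ModelSpec("alcohol", [E("outdegree"),
                                     E("linear", target="behavior")])
    with pytest.raises(ValueError, match="no observed change"):
        sn.fit(panel, beh, model, options=sn.FitOptions(seed=0))


def test_result_frame_and_stars():
    res = sn.EstimationResult(
        effect_keys=["net:outdegree", "net:reciprocity"],
        theta=np.array([-2.0, 0.01]), se=np.array([0.1, 0.5]),
        rate_labels=["rate:net:g:p1"], rates=np.array([3.0]),
        rate_se=np.array([0.2]), conv_t=np.zeros(3),
        labels=["rate:net:g:p1", "net:outdegree", "net:reciprocity"],
        converged=True, n_iterations=10, seed=0)
    assert res.stars() == ["***", ""]
    frame = res.to_frame()
    assert set(frame.columns) == {"parameter", "b", "se", "sig", "conv_t"}
    assert len(frame) == 3
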