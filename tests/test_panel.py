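import numpy as np
import pandas as pd
import pytest

import sabnet as sn
from sabnet.panel import MISSING, PRESENT


# ---------------------------------------------------------------------------
# transforms

@pytest.mark.parametrize("raw, capped", [
    ([1, 4, 7, 7], [1, 4, 6, 6]),  # seven-point intensity capped at six
    ([2, 3], [2, 3]),
    ([np.nan, np.nan], [np.nan, np.nan]),
])
def test_top_code(raw, capped):
    out = sn.top_code(raw, cap=6)
    np.testing.assert_array_equal(out, np.asarray(capped, dtype=float))


def test_top_code_rejects_non_integers():
    with pytest.raises(ValueError, match="integer"):
        sn.top_code([1.5, 2.0])


def test_center_symmetric_and_constant():
    np.testing.assert_allclose(sn.center([1, 2, 3, 4]),
                               [-1.5, -0.5, 0.5, 1.5])
    np.testing.assert_allclose(sn.center([3, 3]), [0, 0])


def test_center_group_means_are_zero():
    vals = np.array([1.0, 2.0, 10.0, 14.0, np.nan])
    groups = np.array([0, 0, 1, 1, 1])
    out = sn.center(vals, groups)
    assert abs(np.nanmean(out[groups == 0])) < 1e-12
    assert abs(np.nanmean(out[groups == 1])) < 1e-12
    assert np.isnan(out[4])


def test_center_empty_errors():
    with pytest.raises(ValueError):
        sn.center([np.nan, np.nan])


# ---------------------------------------------------------------------------
# construction and invariants

def test_panel_construction_counts():
    adj = np.zeros((3, 4, 4), dtype=np.int8)
    for i, j in ((0, 1), (1, 0), (1, 2), (2, 3), (0, 2)):
        adj[1, i, j] = 1
    panel = sn.NetworkPanel(["w1", "w2", "w3"], adj, list("abcd"))
    assert panel.tie_count(1) == 5
    assert (np.diagonal(panel.adjacency[1]) == 0).all()


def test_panel_rejects_self_ties_and_bad_codes():
    adj = np.zeros((1, 3, 3), dtype=np.int8)
    adj[0, 1, 1] = 1
    with pytest.raises(ValueError, match="self-ties"):
        sn.NetworkPanel(["w1"], adj, list("abc"))
    adj = np.full((1, 3, 3), 2, dtype=np.int8)
    with pytest.raises(ValueError, match="cells"):
        sn.NetworkPanel(["w1"], adj, list("abc"))


def test_behavior_panel_range_check():
    with pytest.raises(ValueError, match="integers"):
        sn.BehaviorPanel("alcohol", np.array([[0.0, 3.0]]))
    with pytest.raises(ValueError, match="integers"):
        sn.BehaviorPanel("alcohol", np.array([[7.0, 3.0]]))


def test_schedule_requires_ordered_interval():
    with pytest.raises(ValueError):
        sn.CompositionSchedule(np.array([1.0]), np.array([0.5]))


# ---------------------------------------------------------------------------
# I/O

def _toy_panel(missing_actor_wave2=True):
    rng = np.random.default_rng(42)
    n, W = 8, 3
    adj = np.zeros((W, n, n), dtype=np.int8)
    for w in range(W):
        m = (rng.random((n, n)) < 0.25).astype(np.int8)
        np.fill_diagonal(m, 0)
        adj[w] = m
    if missing_actor_wave2:
        adj[1, 3, :] = MISSING
        adj[1, 3, 3] = 0
    ids = [f"a{k}" for k in range(n)]
    panel = sn.NetworkPanel([f"w{w+1}" for w in range(W)], adj, ids)
    table = sn.ActorTable(pd.DataFrame(
        {"sex": rng.integers(0, 2, n), "grade": rng.integers(9, 13, n)},
        index=pd.Index(ids, name="actor_id")))
    scores = rng.integers(1, 7, (W, n)).astype(float)
    scores[0, 2] = np.nan
    beh = sn.BehaviorPanel("alcohol", scores)
    joins = np.zeros(n)
    leaves = np.full(n, 2.0)
    joins[5] = 0.7
    sched = sn.CompositionSchedule(joins, leaves)
    return panel, table, beh, sched


def test_round_trip(tmp_path):
    panel, table, beh, sched = _toy_panel()
    sn.write_panel(tmp_path, panel, table, {"alcohol": beh}, sched)
    edges = [tmp_path / f"panel_edges_w{w+1}.csv" for w in range(3)]
    p2, t2, b2, s2 = sn.read_panel(
        edges, tmp_path / "panel_attributes.csv", ["alcohol"],
        behavior_path=tmp_path / "panel_behavior.csv",
        schedule_path=tmp_path / "panel_schedule.json")
    np.testing.assert_array_equal(p2.adjacency, panel.adjacency)
    assert p2.actor_ids == panel.actor_ids
    np.testing.assert_array_equal(
        np.isnan(b2["alcohol"].scores), np.isnan(beh.scores))
    np.testing.assert_array_equal(
        np.nan_to_num(b2["alcohol"].scores), np.nan_to_num(beh.scores))
    np.testing.assert_allclose(s2.joins, sched.joins)
    np.testing.assert_allclose(s2.leaves, sched.leaves)


def test_nonrespondent_row_is_missing(tmp_path):
    (tmp_path / "attrs.csv").write_text(
        "actor_id,sex\na1,0\na2,1\na3,0\na4,1\n")
    (tmp_path / "b.csv").write_text(
        "actor_id,alcohol_w1\na1,1\na2,2\na3,3\na4,\n")
    # actor a3 files no row at this wave -> outgoing cells missing
    (tmp_path / "e1.csv").write_text(
        "wave,from,to\n1,a1,a2\n1,a2,\n1,a4,a1\n")
    panel, _, beh, _ = sn.read_panel(
        [tmp_path / "e1.csv"], tmp_path / "attrs.csv", ["alcohol"],
        behavior_path=tmp_path / "b.csv")
    assert (panel.adjacency[0, 2, [0, 1, 3]] == MISSING).all()
    assert panel.adjacency[0, 1, 0] == 0  # explicit empty respondent
    assert panel.adjacency[0, 0, 1] == PRESENT
    assert panel.missing_fraction(0) == pytest.approx(0.25)
    assert np.isnan(beh["alcohol"].scores[0, 3])


def test_duplicate_edge_dedup_with_warning(tmp_path):
    (tmp_path / "attrs.csv").write_text(
        "actor_id,sex,alcohol_w1\na1,0,1\na2,1,2\n")
    (tmp_path / "e1.csv").write_text(
        "wave,from,to\n1,a1,a2\n1,a1,a2\n")
    with pytest.warns(UserWarning, match="duplicate"):
        panel, _, _, _ = sn.read_panel(
            [tmp_path / "e1.csv"], tmp_path / "attrs.csv", ["alcohol"])
    assert panel.tie_count(0) == 1


@pytest.mark.parametrize("row, msg", [
    ("1,a1,a1", "self-tie"),
    ("1,zz,a2", "unknown actor id"),
    ("1,a1,zz", "unknown actor id"),
])
def test_bad_edge_rows_error(tmp_path, row, msg):
    (tmp_path / "attrs.csv").write_text(
        "actor_id,sex,alcohol_w1\na1,0,1\na2,1,2\n")
    (tmp_path / "e1.csv").write_text(f"wave,from,to\n{row}\n")
    with pytest.raises(ValueError, match=msg):
        sn.read_panel([tmp_path / "e1.csv"], tmp_path / "attrs.csv",
                      ["alcohol"])
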