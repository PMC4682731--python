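import numpy as np
import pytest

import sabnet as sn
from conftest import all_behavior_effects, all_network_effects, random_state


E = sn.EffectSpec


# ---------------------------------------------------------------------------
# worked-example statistics (Fixture A, centering disabled)

@pytest.mark.parametrize("effect, i, expected", [
    (E("outdegree"), 0, 2.0),
    (E("reciprocity"), 0, 1.0),  # only 1<->2 is mutual
    (E("transitive_triplets"), 0, 1.0),  # 1->2, 2->3, 1->3
    (E("three_cycles"), 0, 0.0),
    (E("indegree_popularity_sqrt"), 0, np.sqrt(1) + np.sqrt(2)),
    (E("ego", covariate="v"), 0, 1.0 * 2),
    (E("alter", covariate="v"), 0, 2.0 + 3.0),
    (E("ego_x_alter", covariate="v"), 0, 1.0 * (2.0 + 3.0)),
    (E("same", covariate="z"), 2, 1.0),  # 3->4 and z3 == z4
    (E("average_alter", target="behavior"), 0, 1.0 * (2 + 3) / 2),
    (E("linear", target="behavior"), 2, 3.0),
    (E("quadratic", target="behavior"), 2, 9.0),
])
def test_fixture_a_statistics(fixture_a, effect, i, expected):
    assert sn.statistic(effect, fixture_a, i) == pytest.approx(expected)


def test_empty_network_statistics_vanish():
    st = sn.StateView(np.zeros((5, 5), dtype=np.int8),
                      np.full(5, 3.0), {"v": np.arange(5.0)}, z_name="z")
    for eff in all_network_effects() + all_behavior_effects():
        if eff.name in ("linear", "quadratic", "covariate"):
            continue  # these do not reference ties
        for i in range(5):
            assert sn.statistic(eff, st, i) == 0.0


def test_average_alter_isolate_is_zero(fixture_a):
    # actor 4 nominates nobody
    eff = E("average_alter", target="behavior")
    assert sn.statistic(eff, fixture_a, 3) == 0.0


# ---------------------------------------------------------------------------
# change-score oracle: incremental gain == brute-force before/after

def brute_tie_gain(spec_list, state, i, j):
    creating = state.x[i, j] == 0
    after = state.copy()
    after.x[i, j] = 1 - after.x[i, j]
    total = 0.0
    for eff in spec_list:
        if eff.target != "network":
            continue
        if eff.role == "creation" and not creating:
            continue
        if eff.role == "endowment" and creating:
            continue
        delta = sn.statistic(eff, after, i) - sn.statistic(eff, state, i)
        total += eff.parameter * delta
    return total


def brute_behavior_gain(spec_list, state, i, delta):
    after = state.copy()
    after.z[i] += delta
    total = 0.0
    for eff in spec_list:
        if eff.target != "behavior":
            continue
        total += eff.parameter * (sn.statistic(eff, after, i)
                                  - sn.statistic(eff, state, i))
    return total


def test_change_scores_match_brute_force():
    rng = np.random.default_rng(7)
    effects = all_network_effects(0.7) + all_behavior_effects(0.7)
    for _ in range(150):
        st = random_state(rng)
        n = st.n
        i = int(rng.integers(n))
        gains = sn.tie_gain_vector(effects, st, i)
        for j in range(n):
            if j == i:
                assert gains[j] == -np.inf
                continue
            assert gains[j] == pytest.approx(
                brute_tie_gain(effects, st, i, j), abs=1e-9)
            assert sn.tie_change_gain(effects, st, i, j) == pytest.approx(
                gains[j], abs=1e-9)
        for d in (-1, 0, 1):
            if not 1 <= st.z[i] + d <= 6:
                continue
            assert sn.behavior_change_gain(effects, st, i, d) == \
                pytest.approx(brute_behavior_gain(effects, st, i, d),
                              abs=1e-9)


def test_role_gating_creation_and_endowment(fixture_a):
    creation = [E("ego_x_alter", covariate="v", role="creation",
                  parameter=1.0)]
    endowment = [E("ego_x_alter", covariate="v", role="endowment",
                   parameter=1.0)]
    # 1->2 exists: dissolving it gets no creation contribution
    assert sn.tie_change_gain(creation, fixture_a, 0, 1) == 0.0
    assert sn.tie_change_gain(endowment, fixture_a, 0, 1) != 0.0
    # 1->4 absent: creating it gets no endowment contribution
    assert sn.tie_change_gain(endowment, fixture_a, 0, 3) == 0.0
    assert sn.tie_change_gain(creation, fixture_a, 0, 3) != 0.0


def test_outdegree_gain_signs(fixture_a):
    effects = [E("outdegree", parameter=1.0)]
    assert sn.tie_change_gain(effects, fixture_a, 0, 3) == 1.0  # create
    assert sn.tie_change_gain(effects, fixture_a, 0, 1) == -1.0  # dissolve


def test_zero_parameters_zero_gain(fixture_a):
    effects = all_network_effects(0.0)
    for j in (1, 2, 3):
        assert sn.tie_change_gain(effects, fixture_a, 0, j) == 0.0


def test_self_toggle_errors(fixture_a):
    with pytest.raises(ValueError):
        sn.tie_change_gain([E("outdegree", parameter=1.0)], fixture_a, 1, 1)


@pytest.mark.parametrize("delta, z, expected", [
    (0, 3.0, 0.0),
    (1, 3.0, 1.0),  # linear shape
])
def test_behavior_linear_gain(fixture_a, delta, z, expected):
    effects = [E("linear", target="behavior", parameter=1.0)]
    assert sn.behavior_change_gain(effects, fixture_a, 2, delta) == expected


def test_behavior_quadratic_gain_raw_scale(fixture_a):
    effects = [E("quadratic", target="behavior", parameter=1.0)]
    # raw z_i = 3, step +1: 16 - 9 = 7
    assert sn.behavior_change_gain(effects, fixture_a, 2, 1) == 7.0


# ---------------------------------------------------------------------------
# invariants

def test_reciprocity_total_is_twice_mutual_count():
    rng = np.random.default_rng(11)
    eff = E("reciprocity")
    for _ in range(50):
        st = random_state(rng)
        total = sn.statistic_total(eff, st)
        mutual = sn.dyad_census(st.x).mutual
        assert total == 2 * mutual


def test_same_with_constant_covariate_equals_outdegree():
    rng = np.random.default_rng(12)
    for _ in range(30):
        st = random_state(rng)
        st.covariates["const"] = np.ones(st.n)
        same = E("same", covariate="const")
        outd = E("outdegree")
        for i in range(st.n):
            assert sn.statistic(same, st, i) == sn.statistic(outd, st, i)


def test_ego_x_alter_invariant_under_relabeling():
    rng = np.random.default_rng(13)
    st = random_state(rng, n=6)
    perm = rng.permutation(6)
    st2 = sn.StateView(st.x[np.ix_(perm, perm)], st.z[perm],
                       {"v": st.covariates["v"][perm]}, z_name="z",
                       means=dict(st.means))
    eff = E("ego_x_alter", covariate="v")
    total1 = sn.statistic_total(eff, st)
    total2 = sn.statistic_total(eff, st2)
    assert total1 == pytest.approx(total2)


def test_vectorized_totals_match_scalar():
    rng = np.random.default_rng(14)
    for _ in range(40):
        st = random_state(rng)
        for eff in all_network_effects() + all_behavior_effects():
            vec = sn.statistic_per_actor(eff, st)
            ref = [sn.statistic(eff, st, i) for i in range(st.n)]
            np.testing.assert_allclose(vec, ref)


# ---------------------------------------------------------------------------
# specification validation

def test_effect_spec_validation():
    with pytest.raises(ValueError, match="unknown network effect"):
        E("gwesp")
    with pytest.raises(ValueError, match="covariate"):
        E("ego")  # needs one
    with pytest.raises(ValueError, match="does not take"):
        E("outdegree", covariate="v")
    with pytest.raises(ValueError, match="network effects only"):
        E("average_alter", target="behavior", role="creation")


def test_model_rejects_duplicates():
    with pytest.raises(ValueError, match="duplicated"):
        sn.ModelSpec("alcohol", [E("outdegree"), E("outdegree")])


def test_model_yaml_round_trip(tmp_path):
    cfg = {
        "behavior": "alcohol",
        "center_behavior": True,
        "effects": [
            {"name": "outdegree", "initial": -1.5},
            {"name": "ego_x_alter", "covariate": "alcohol",
             "role": "creation"},
            {"name": "average_alter", "target": "behavior"},
            {"name": "quadratic", "target": "behavior", "fixed": True},
        ],
    }
    import yaml
    path = tmp_path / "model.yaml"
    path.write_text(yaml.safe_dump(cfg))
    model = sn.load_model_yaml(path)
    assert model.behavior == "alcohol"
    assert len(model.effects) == 4
    assert model.effects[0].parameter == -1.5
    assert model.effects[1].role == "creation"
    assert model.effects[3].fixed
    assert len(model.free_effects) == 3
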