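import numpy as np
import pytest

import sabnet as sn


@pytest.fixture
def fixture_a():
    """4-actor worked example: ties 1->2, 2->1, 2->3, 3->4, 1->3."""
    return sn.fixture_a_state()


def random_state(rng, n=None, p=0.4, with_covariate=True):
    """A small random StateView for oracle comparisons."""
    if n is None:
        n = int(rng.integers(3, 9))
    x = (rng.random((n, n)) < p).astype(np.int8)
    np.fill_diagonal(x, 0)
    z = rng.integers(1, 7, n).astype(float)
    cov = {"v": rng.integers(0, 4, n).astype(float)} if with_covariate else {}
    means = {"z": float(z.mean()), "v": 1.5} if with_covariate else {}
    return sn.StateView(x, z, cov, z_name="z", means=means)


def all_network_effects(theta=1.0):
    E = sn.EffectSpec
    return [
        E("outdegree", parameter=theta),
        E("reciprocity", parameter=theta),
        E("transitive_triplets", parameter=theta),
        E("three_cycles", parameter=theta),
        E("indegree_popularity_sqrt", parameter=theta),
        E("ego", covariate="v", parameter=theta),
        E("alter", covariate="v", parameter=theta),
        E("ego_x_alter", covariate="v", parameter=theta),
        E("same", covariate="v", parameter=theta),
        E("ego", covariate="z", parameter=theta),
        E("alter", covariate="z", parameter=theta),
        E("ego_x_alter", covariate="z", parameter=theta),
    ]


def all_behavior_effects(theta=1.0):
    E = sn.EffectSpec
    return [
        E("linear", target="behavior", parameter=theta),
        E("quadratic", target="behavior", parameter=theta),
        E("indegree", target="behavior", parameter=theta),
        E("outdegree", target="behavior", parameter=theta),
        E("average_alter", target="behavior", parameter=theta),
        E("covariate", target="behavior", covariate="v", parameter=theta),
    ]
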