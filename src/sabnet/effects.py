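"""Effect statistics for the actor-oriented co-evolution model.

Each effect is a per-actor statistic s_ik(x, v, z) entering either the
network objective function (selection) or the behavior objective
function (influence).  Network effects may additionally be restricted by
role: an *evaluation* effect weighs every tie state, a *creation* effect
counts only toward forming a new tie, and an *endowment* effect only
toward keeping (not dissolving) an existing one.  The creation/endowment
split is what separates selection into new-friendship formation versus
continuation of existing friendships.

Notation: x is the directed 0/1 adjacency (row i = ego's nominations),
v a covariate, z the modeled ordinal behavior.  Covariates and behavior
enter ego/alter/interaction and influence statistics centered at a
configurable mean; the ``same`` effect matches raw values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

NETWORK_EFFECTS = frozenset({
    "outdegree", "reciprocity", "transitive_triplets", "three_cycles",
    "indegree_popularity_sqrt", "ego", "alter", "ego_x_alter", "same",
})
BEHAVIOR_EFFECTS = frozenset({
    "linear", "quadratic", "indegree", "outdegree", "average_alter",
    "covariate",
})
#: effects whose formula references a covariate v
_NEEDS_COVARIATE = frozenset({"ego", "alter", "ego_x_alter", "same",
                              "covariate"})
ROLES = ("evaluation", "creation", "endowment")


@dataclass(frozen=True)
class EffectSpec:
    """One model term: an effect statistic with its parameter (logit)."""

    name: str
    target: str = "network"  # network | behavior
    role: str = "evaluation"  # evaluation | creation | endowment
    covariate: str | None = None
    parameter: float = 0.0
    fixed: bool = False
    initial: float = 0.0

    def __post_init__(self) -> None:
        pool = NETWORK_EFFECTS if self.target == "network" else (
            BEHAVIOR_EFFECTS if self.target == "behavior" else None)
        if pool is None:
            raise ValueError(f"unknown target {self.target!r}")
        if self.name not in pool:
            raise ValueError(
                f"unknown {self.target} effect {self.name!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.role != "evaluation" and self.target != "network":
            raise ValueError(
                "creation/endowment roles apply to network effects only")
        needs_v = (self.name in _NEEDS_COVARIATE
                   and self.target == "network") or self.name == "covariate"
        if needs_v and self.covariate is None:
            raise ValueError(f"effect {self.name!r} requires a covariate")
        if not needs_v and self.covariate is not None:
            raise ValueError(
                f"effect {self.name!r} does not take a covariate")

    @property
    def key(self) -> str:
        """Unique display key, e.g. ``net:ego_x_alter[alcohol]/creation``."""
        tag = "net" if self.target == "network" else "beh"
        cov = f"[{self.covariate}]" if self.covariate else ""
        role = "" if self.role == "evaluation" else f"/{self.role}"
        return f"{tag}:{self.name}{cov}{role}"


@dataclass
class StateView:
    """A snapshot of network, behavior, covariates and activity flags.

    ``z`` holds the modeled behavior on its raw 1..6 scale; ``means``
    maps covariate/behavior labels to the value subtracted before a
    centered statistic is evaluated (absent label = no centering).
    """

    x: np.ndarray
    z: np.ndarray
    covariates: dict[str, np.ndarray] = field(default_factory=dict)
    active: np.ndarray | None = None
    z_name: str = "z"
    means: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.int8)
        self.z = np.asarray(self.z, dtype=float)
        n = self.x.shape[0]
        if self.x.shape != (n, n) or self.z.shape != (n,):
            raise ValueError("inconsistent state dimensions")
        if self.active is None:
            self.active = np.ones(n, dtype=bool)
        self.active = np.asarray(self.active, dtype=bool)

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def raw(self, label: str) -> np.ndarray:
        if label in (self.z_name, "z"):
            return self.z
        try:
            return self.covariates[label]
        except KeyError:
            raise KeyError(f"covariate {label!r} not in state") from None

    def centered(self, label: str) -> np.ndarray:
        return self.raw(label) - self.means.get(label, 0.0)

    def z_centered(self) -> np.ndarray:
        return self.z - self.means.get(self.z_name, 0.0)

    def copy(self) -> "StateView":
        return StateView(self.x.copy(), self.z.copy(), dict(self.covariates),
                         self.active.copy(), self.z_name, dict(self.means))


# ---------------------------------------------------------------------------
# full statistics

def statistic(effect: EffectSpec, state: StateView, i: int) -> float:
    """Evaluate one effect statistic s_ik for actor ``i``.

    Inactive actors contribute nothing (statistic 0).
    """
    if not state.active[i]:
        return 0.0
    x = state.x
    r = x[i].astype(float)
    name = effect.name
    if effect.target == "network":
        if name == "outdegree":
            return float(r.sum())
        if name == "reciprocity":
            return float(r @ x[:, i])
        if name == "transitive_triplets":
            return float(r @ (x @ r))
        if name == "three_cycles":
            return float(r @ (x @ x[:, i].astype(float)))
        if name == "indegree_popularity_sqrt":
            indeg = x.sum(axis=0, dtype=float)
            return float(r @ np.sqrt(indeg))
        v = state.centered(effect.covariate)
        if name == "ego":
            return float(v[i] * r.sum())
        if name == "alter":
            return float(r @ v)
        if name == "ego_x_alter":
            return float(v[i] * (r @ v))
        if name == "same":
            vr = state.raw(effect.covariate)
            return float(r @ (vr == vr[i]).astype(float))
    else:
        zc = state.z_centered()
        if name == "linear":
            return float(zc[i])
        if name == "quadratic":
            return float(zc[i] ** 2)
        if name == "indegree":
            return float(zc[i] * x[:, i].sum())
        if name == "outdegree":
            return float(zc[i] * r.sum())
        if name == "average_alter":
            deg = r.sum()
            if deg == 0:
                return 0.0
            return float(zc[i] * (r @ zc) / deg)
        if name == "covariate":
            return float(zc[i] * state.centered(effect.covariate)[i])
    raise ValueError(f"unhandled effect {effect.key}")  # pragma: no cover


def statistic_total(effect: EffectSpec, state: StateView,
                    mask: np.ndarray | None = None) -> float:
    """Sum of the statistic over (masked) active actors."""
    idx = np.flatnonzero(state.active if mask is None
                         else (state.active & mask))
    return float(sum(statistic(effect, state, int(i)) for i in idx))


def statistic_per_actor(effect: EffectSpec, state: StateView) -> np.ndarray:
    """Vectorized per-actor statistic; equals :func:`statistic` actor-wise.

    Used on the estimator's hot path; the scalar implementation above is
    the reference it is tested against.
    """
    x = state.x.astype(float)
    name = effect.name
    if effect.target == "network":
        if name == "outdegree":
            vals = x.sum(axis=1)
        elif name == "reciprocity":
            vals = (x * x.T).sum(axis=1)
        elif name == "transitive_triplets":
            vals = np.einsum("ij,jh,ih->i", x, x, x)
        elif name == "three_cycles":
            vals = np.einsum("ij,jh,hi->i", x, x, x)
        elif name == "indegree_popularity_sqrt":
            vals = x @ np.sqrt(x.sum(axis=0))
        else:
            v = state.centered(effect.covariate)
            if name == "ego":
                vals = v * x.sum(axis=1)
            elif name == "alter":
                vals = x @ v
            elif name == "ego_x_alter":
                vals = v * (x @ v)
            elif name == "same":
                vr = state.raw(effect.covariate)
                vals = (x * (vr[:, None] == vr[None, :])).sum(axis=1)
            else:  # pragma: no cover
                raise ValueError(f"unhandled effect {effect.key}")
    else:
        zc = state.z_centered()
        if name == "linear":
            vals = zc.copy()
        elif name == "quadratic":
            vals = zc ** 2
        elif name == "indegree":
            vals = zc * x.sum(axis=0)
        elif name == "outdegree":
            vals = zc * x.sum(axis=1)
        elif name == "average_alter":
            deg = x.sum(axis=1)
            s = x @ zc
            vals = zc * np.divide(s, deg, out=np.zeros_like(s),
                                  where=deg > 0)
        elif name == "covariate":
            vals = zc * state.centered(effect.covariate)
        else:  # pragma: no cover
            raise ValueError(f"unhandled effect {effect.key}")
    return np.where(state.active, vals, 0.0)


# ---------------------------------------------------------------------------
# change scores
#
# For a candidate toggle of tie i->j the gain of each effect is the
# statistic after minus before, computed incrementally in O(degree);
# the brute-force before/after recomputation is kept as the test oracle.

def _tie_deltas(effect: EffectSpec, state: StateView, i: int,
                r: np.ndarray | None = None,
                sign: np.ndarray | None = None) -> np.ndarray:
    """Signed change of s_ik for toggling x[i, j], vectorized over j.

    ``r``/``sign`` may be passed in to share work across effects.
    """
    x = state.x
    if r is None:
        r = x[i].astype(float)
    if sign is None:
        sign = 1.0 - 2.0 * r  # +1 where creating, -1 where dissolving
    name = effect.name
    if name == "outdegree":
        return sign
    if name == "reciprocity":
        return sign * x[:, i]
    if name == "transitive_triplets":
        # toggled tie closes two-paths i->h->j and i->h<-... both orders
        return sign * (x @ r + r @ x)
    if name == "three_cycles":
        return sign * (x @ x[:, i].astype(float))
    if name == "indegree_popularity_sqrt":
        indeg = x.sum(axis=0, dtype=float)
        return np.where(r == 0, np.sqrt(indeg + 1.0), -np.sqrt(indeg))
    v = state.centered(effect.covariate)
    if name == "ego":
        return sign * v[i]
    if name == "alter":
        return sign * v
    if name == "ego_x_alter":
        return sign * v[i] * v
    if name == "same":
        vr = state.raw(effect.covariate)
        return sign * (vr == vr[i]).astype(float)
    raise ValueError(f"unhandled network effect {effect.key}")


def tie_gain_vector(spec_list: Sequence[EffectSpec], state: StateView,
                    i: int) -> np.ndarray:
    """Objective-function gain of toggling i->j, for every j at once.

    Role gating follows the new/old decomposition: creation effects
    count only where the toggle would create a tie (x_ij = 0), endowment
    effects only where it would dissolve one (x_ij = 1).  Entries for
    j = i and inactive j are set to -inf (never chosen).
    """
    x = state.x
    gains = np.zeros(state.n)
    r = x[i].astype(float)
    sign = 1.0 - 2.0 * r
    creating = r == 0
    for eff in spec_list:
        if eff.target != "network" or eff.parameter == 0.0:
            continue
        d = eff.parameter * _tie_deltas(eff, state, i, r, sign)
        if eff.role == "creation":
            d = np.where(creating, d, 0.0)
        elif eff.role == "endowment":
            d = np.where(creating, 0.0, d)
        gains += d
    gains[i] = -np.inf
    gains[~state.active] = -np.inf
    return gains


def tie_change_gain(spec_list: Sequence[EffectSpec], state: StateView,
                    i: int, j: int) -> float:
    """Gain (logit) of toggling the single tie i->j."""
    if i == j:
        raise ValueError("self-ties cannot change")
    if not (state.active[i] and state.active[j]):
        raise ValueError("both actors must be active")
    x = state.x
    creating = x[i, j] == 0
    total = 0.0
    for eff in spec_list:
        if eff.target != "network" or eff.parameter == 0.0:
            continue
        if eff.role == "creation" and not creating:
            continue
        if eff.role == "endowment" and creating:
            continue
        total += eff.parameter * float(_tie_deltas(eff, state, i)[j])
    return total


def behavior_change_gain(spec_list: Sequence[EffectSpec], state: StateView,
                         i: int, delta: int) -> float:
    """Gain (logit) of moving actor i's behavior by ``delta`` levels."""
    if delta == 0:
        return 0.0
    x = state.x
    zc = state.z_centered()
    zi = zc[i]
    total = 0.0
    for eff in spec_list:
        if eff.target != "behavior" or eff.parameter == 0.0:
            continue
        name = eff.name
        if name == "linear":
            d = float(delta)
        elif name == "quadratic":
            d = (zi + delta) ** 2 - zi ** 2
        elif name == "indegree":
            d = delta * float(x[:, i].sum())
        elif name == "outdegree":
            d = delta * float(x[i].sum())
        elif name == "average_alter":
            r = x[i].astype(float)
            deg = r.sum()
            d = 0.0 if deg == 0 else delta * float(r @ zc) / deg
        elif name == "covariate":
            d = delta * float(state.centered(eff.covariate)[i])
        else:  # pragma: no cover
            raise ValueError(f"unhandled behavior effect {eff.key}")
        total += eff.parameter * d
    return float(total)


def behavior_gain_vector(spec_list: Sequence[EffectSpec], state: StateView,
                         i: int, deltas: Sequence[int]) -> np.ndarray:
    """:func:`behavior_change_gain` for several steps at once."""
    x = state.x
    zmean = state.means.get(state.z_name, 0.0)
    zi = state.z[i] - zmean
    d = np.asarray(deltas, dtype=float)
    total = np.zeros_like(d)
    for eff in spec_list:
        if eff.target != "behavior" or eff.parameter == 0.0:
            continue
        name = eff.name
        if name == "linear":
            g = d
        elif name == "quadratic":
            g = (zi + d) ** 2 - zi ** 2
        elif name == "indegree":
            g = d * float(x[:, i].sum())
        elif name == "outdegree":
            g = d * float(x[i].sum())
        elif name == "average_alter":
            r = x[i]
            deg = float(r.sum())
            g = (d * (float(r @ state.z) - deg * zmean) / deg
                 if deg > 0 else 0.0 * d)
        elif name == "covariate":
            g = d * float(state.centered(eff.covariate)[i])
        else:  # pragma: no cover
            raise ValueError(f"unhandled behavior effect {eff.key}")
        total += eff.parameter * g
    return total


# ---------------------------------------------------------------------------
# model specification

@dataclass
class ModelSpec:
    """A co-evolution model: the behavior variable plus its effect list."""

    behavior: str
    effects: list[EffectSpec]
    center_behavior: bool = True
    center_covariates: bool = True

    def __post_init__(self) -> None:
        keys = [e.key for e in self.effects]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicated effects: {dupes}")

    @property
    def free_effects(self) -> list[EffectSpec]:
        return [e for e in self.effects if not e.fixed]

    def with_parameters(self, theta: Sequence[float]) -> "ModelSpec":
        """Copy with free-effect parameters replaced by ``theta``."""
        theta = list(theta)
        if len(theta) != len(self.free_effects):
            raise ValueError("theta length mismatch")
        it = iter(theta)
        effs = [e if e.fixed else replace(e, parameter=float(next(it)))
                for e in self.effects]
        return ModelSpec(self.behavior, effs, self.center_behavior,
                         self.center_covariates)


def model_from_dict(cfg: dict) -> ModelSpec:
    """Build a ModelSpec from a plain dict (the YAML config schema)."""
    effects = []
    for item in cfg.get("effects", []):
        effects.append(EffectSpec(
            name=item["name"],
            target=item.get("target", "network"),
            role=item.get("role", "evaluation"),
            covariate=item.get("covariate"),
            parameter=float(item.get("initial", item.get("parameter", 0.0))),
            fixed=bool(item.get("fixed", False)),
            initial=float(item.get("initial", 0.0)),
        ))
    return ModelSpec(
        behavior=cfg.get("behavior", "alcohol"),
        effects=effects,
        center_behavior=bool(cfg.get("center_behavior", True)),
        center_covariates=bool(cfg.get("center_covariates", True)),
    )


def load_model_yaml(path: str | Path) -> ModelSpec:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))
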