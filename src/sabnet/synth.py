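"""Synthetic school panels with known ground truth.

Generates longitudinal friendship/drinking panels shaped like a
multi-wave in-school sociometric survey: two school presets (a
predominantly one-race mid-sized school and a larger heterogeneous
one), three waves, up to 5 male + 5 female nominations, sparse
sex-homophilous networks, ordinal drinking on 1..6 co-evolving with the
ties, wave-level actor nonresponse, a small restricted-nomination
subset, and composition change.  The first wave is drawn from a dyadic
logistic model with homophily; later waves are forward-simulated under
a true actor-oriented model, so every generated panel carries exact
ground-truth parameters for recovery studies.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .effects import EffectSpec, ModelSpec, StateView, tie_gain_vector
from .panel import (MISSING, ActorTable, BehaviorPanel, CompositionSchedule,
                    NetworkPanel, write_panel)
from .sim import RateSchedule, forward_simulate_panel

RACE_PRESETS = {
    # a ~93%-one-race school vs. a heterogeneous school
    "homogeneous": {"white": 0.93, "black": 0.02, "hispanic": 0.03,
                    "asian": 0.02},
    "heterogeneous": {"white": 0.06, "black": 0.23, "hispanic": 0.39,
                      "asian": 0.32},
}

#: true-model defaults; keys use the effect-key grammar
#: ``net:<name>[cov][/role]`` / ``beh:<name>[cov]``
DEFAULT_TRUE_PARAMETERS: dict[str, float] = {
    "net:outdegree": -3.3,
    "net:reciprocity": 2.0,
    "net:transitive_triplets": 0.25,
    "net:same[sex]": 0.45,
    "net:same[grade]": 0.55,
    "net:ego_x_alter[alcohol]": 0.15,
    "beh:linear": 0.0,
    "beh:quadratic": -0.25,
    "beh:average_alter": 0.4,
}

_KEY_RE = re.compile(
    r"^(net|beh):(\w+)(?:\[(\w+)\])?(?:/(creation|endowment))?$")


def effects_from_parameters(params: dict[str, float]) -> list[EffectSpec]:
    """Build an effect list from a {effect-key: value} mapping."""
    out = []
    for key, value in params.items():
        m = _KEY_RE.match(key)
        if not m:
            raise ValueError(f"malformed effect key {key!r}")
        tag, name, cov, role = m.groups()
        out.append(EffectSpec(
            name=name,
            target="network" if tag == "net" else "behavior",
            role=role or "evaluation",
            covariate=cov,
            parameter=float(value)))
    return out


@dataclass
class SchoolConfig:
    """Shape of one synthetic school; defaults are the study conditions."""

    n_actors: int = 150
    n_waves: int = 3
    sex_ratio: float = 0.49  # fraction female
    grades: tuple[int, ...] = (9, 10, 11, 12)
    race_preset: str = "homogeneous"
    true_parameters: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_PARAMETERS))
    rate_network: float = 4.0
    rate_behavior: float = 1.2
    target_avg_degree: float = 4.0
    missing_rates: tuple[float, ...] = (0.25, 0.05, 0.20)
    joiner_fraction: float = 0.03
    leaver_fraction: float = 0.03
    restricted_fraction: float = 0.05
    behavior_name: str = "alcohol"
    behavior_init_probs: tuple[float, ...] = (0.42, 0.18, 0.15, 0.10,
                                              0.08, 0.07)
    nomination_cap: int = 5
    name: str = "school"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_actors < 20:
            raise ValueError("need at least 20 actors")
        if self.race_preset not in RACE_PRESETS:
            raise ValueError(f"unknown race preset {self.race_preset!r}")
        for frac in (self.sex_ratio, self.joiner_fraction,
                     self.leaver_fraction, self.restricted_fraction,
                     *self.missing_rates):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.target_avg_degree >= self.n_actors - 1:
            raise ValueError("target density infeasible for this n")

    def true_model(self) -> ModelSpec:
        return ModelSpec(self.behavior_name,
                         effects_from_parameters(self.true_parameters))


@dataclass
class GroundTruth:
    """The config plus the complete (pre-masking) realized panels."""

    config: SchoolConfig
    panel: NetworkPanel
    behavior: BehaviorPanel
    model: ModelSpec
    rates: RateSchedule


def _draw_covariates(cfg: SchoolConfig, rng: np.random.Generator
                     ) -> ActorTable:
    n = cfg.n_actors
    races = list(RACE_PRESETS[cfg.race_preset])
    probs = np.array([RACE_PRESETS[cfg.race_preset][r] for r in races])
    data = {
        "sex": (rng.random(n) < cfg.sex_ratio).astype(int),  # 1 = female
        "grade": rng.choice(cfg.grades, size=n),
        "race": rng.choice(races, size=n, p=probs / probs.sum()),
        "parent_education": rng.integers(1, 6, size=n),
        "parent_drinking": np.minimum(
            1 + rng.poisson(0.9, size=n), 6),
        "alcohol_easy": (rng.random(n) < 0.30).astype(int),
        "restricted_nomination": (
            rng.random(n) < cfg.restricted_fraction).astype(int),
    }
    for w in range(cfg.n_waves):
        p_smoke = min(0.12 + 0.08 * w, 0.5)
        data[f"smoker_w{w + 1}"] = (rng.random(n) < p_smoke).astype(int)
        data[f"offlist_w{w + 1}"] = rng.poisson(1.6, size=n)
    ids = [f"{cfg.name}_{k + 1:04d}" for k in range(n)]
    return ActorTable(pd.DataFrame(data, index=pd.Index(ids,
                                                        name="actor_id")))


def _initial_network(cfg: SchoolConfig, table: ActorTable, z0: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Dyad-independent logistic draw hitting the target average degree."""
    n = cfg.n_actors
    sex = table.column("sex")
    grade = table.column("grade")
    zc = z0 - z0.mean()
    pars = cfg.true_parameters
    logits = (pars.get("net:same[sex]", 0.0)
              * (sex[:, None] == sex[None, :])
              + pars.get("net:same[grade]", 0.0)
              * (grade[:, None] == grade[None, :])
              + pars.get("net:ego_x_alter[alcohol]", 0.0)
              * np.outer(zc, zc)
              + pars.get("net:reciprocity", 0.0) * 0.1)
    target_p = cfg.target_avg_degree / (n - 1)
    off = ~np.eye(n, dtype=bool)

    def mean_p(alpha: float) -> float:
        sig = 1.0 / (1.0 + np.exp(-(alpha + logits[off])))
        return float(sig.mean())

    lo, hi = -20.0, 5.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < target_p:
            lo = mid
        else:
            hi = mid
    alpha = 0.5 * (lo + hi)
    p = 1.0 / (1.0 + np.exp(-(alpha + logits)))
    x = (rng.random((n, n)) < p).astype(np.int8)
    np.fill_diagonal(x, 0)
    return x


def _censor_caps(x: np.ndarray, sex: np.ndarray, restricted: np.ndarray,
                 cap: int, model: ModelSpec, z: np.ndarray,
                 covs: dict[str, np.ndarray]) -> np.ndarray:
    """Emulate the survey instrument's 5-male/5-female nomination cap.

    Where an actor exceeds the per-sex cap (1 + 1 for the
    restricted-nomination subset), the lowest-valued ties under the
    true objective function are censored from the observed panel.
    """
    out = x.copy()
    n = x.shape[0]
    state = StateView(x, z, covs, z_name=model.behavior)
    for i in range(n):
        limit = 1 if restricted[i] else cap
        gains = None
        for s in (0, 1):
            js = np.flatnonzero((x[i] == 1) & (sex == s))
            if js.size <= limit:
                continue
            if gains is None:
                # toggle gain of an existing tie = -(value of keeping it)
                gains = tie_gain_vector(model.effects, state, i)
            keep = js[np.argsort(gains[js])[:limit]]
            drop = np.setdiff1d(js, keep)
            out[i, drop] = 0
    return out


def generate_school(config: SchoolConfig) -> tuple[
        NetworkPanel, ActorTable, BehaviorPanel, CompositionSchedule,
        GroundTruth]:
    """Generate one school's observed panel plus its ground truth."""
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n, W = cfg.n_actors, cfg.n_waves
    table = _draw_covariates(cfg, rng)
    z0 = rng.choice(np.arange(1, 7), size=n,
                    p=np.asarray(cfg.behavior_init_probs)
                    / np.sum(cfg.behavior_init_probs)).astype(float)
    x0 = _initial_network(cfg, table, z0, rng)

    # composition change: joiners enter after wave 1, leavers exit early
    joins = np.zeros(n)
    leaves = np.full(n, float(W - 1))
    if W > 2:
        k_join = int(cfg.joiner_fraction * n)
        k_leave = int(cfg.leaver_fraction * n)
        movers = rng.permutation(n)[:k_join + k_leave]
        for a in movers[:k_join]:
            joins[a] = rng.uniform(0.3, W - 1.3)
            x0[a, :] = 0
            x0[:, a] = 0
        for a in movers[k_join:]:
            leaves[a] = rng.uniform(joins[a] + 0.5, W - 1 - 0.3)
    schedule = CompositionSchedule(joins, leaves)

    model = cfg.true_model()
    means = {cfg.behavior_name: float(z0.mean())}
    covs = {name: table.column(name)
            for name in ("sex", "grade", "race")}
    start = StateView(x0, z0, covs, schedule.active_at(0.0),
                      z_name=cfg.behavior_name, means=means)
    rates = RateSchedule(np.full(W - 1, cfg.rate_network),
                         np.full(W - 1, cfg.rate_behavior))
    sim_seed = int(rng.integers(2 ** 31))
    true_panel, true_behavior = forward_simulate_panel(
        start, rates, model, W, seed=sim_seed, schedule=schedule,
        actor_ids=table.actor_ids)

    # observed panel: nomination-cap censoring, nonresponse, composition
    sex = table.column("sex").astype(int)
    restricted = table.column("restricted_nomination").astype(bool)
    adjacency = np.zeros_like(true_panel.adjacency)
    scores = true_behavior.scores.copy()
    for w in range(W):
        adjacency[w] = _censor_caps(
            true_panel.adjacency[w], sex, restricted, cfg.nomination_cap,
            model, true_behavior.scores[w], covs)
        present = schedule.active_at(float(w))
        rate = cfg.missing_rates[w % len(cfg.missing_rates)]
        n_miss = int(round(rate * present.sum()))
        miss = rng.choice(np.flatnonzero(present), size=n_miss,
                          replace=False) if n_miss else np.array([], int)
        adjacency[w, miss, :] = MISSING
        scores[w, miss] = np.nan
        adjacency[w, ~present, :] = MISSING
        scores[w, ~present] = np.nan
        idx = np.arange(n)
        adjacency[w, idx, idx] = 0
    panel = NetworkPanel(list(true_panel.waves), adjacency, table.actor_ids)
    behavior = BehaviorPanel(cfg.behavior_name, scores)
    truth = GroundTruth(cfg, true_panel, true_behavior, model, rates)
    return panel, table, behavior, schedule, truth


# ---------------------------------------------------------------------------
# fixture suite

#: the 4-actor worked example used throughout the unit tests
FIXTURE_A_TIES = ((0, 1), (1, 0), (1, 2), (2, 3), (0, 2))
FIXTURE_A_V = (1.0, 2.0, 3.0, 4.0)
FIXTURE_A_Z = (1.0, 2.0, 3.0, 3.0)


def fixture_a_state(centering: bool = False) -> StateView:
    """The 4-actor worked example as a live state."""
    x = np.zeros((4, 4), dtype=np.int8)
    for i, j in FIXTURE_A_TIES:
        x[i, j] = 1
    means = {}
    if centering:
        means = {"v": float(np.mean(FIXTURE_A_V)),
                 "z": float(np.mean(FIXTURE_A_Z))}
    return StateView(x, np.array(FIXTURE_A_Z),
                     {"v": np.array(FIXTURE_A_V)}, z_name="z", means=means)


def recovery_config(n_actors: int = 60, seed: int = 7) -> SchoolConfig:
    """Two-wave recovery panel with the canonical truth parameters."""
    return SchoolConfig(
        n_actors=n_actors, n_waves=2, seed=seed,
        true_parameters={
            "net:outdegree": -2.0,
            "net:reciprocity": 1.5,
            "net:ego_x_alter[alcohol]": 0.15,
            "beh:linear": 0.0,
            "beh:quadratic": -0.3,
            "beh:average_alter": 0.3,
        },
        rate_network=3.0, rate_behavior=1.5,
        target_avg_degree=7.0, missing_rates=(0.0,),
        joiner_fraction=0.0, leaver_fraction=0.0,
        restricted_fraction=0.0, nomination_cap=10 ** 6,
        name="recovery")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def generate_fixture_suite(out_dir: str | Path) -> dict[str, str]:
    """Write the worked example, a recovery panel and a two-school panel.

    Returns a manifest mapping relative file names to SHA-256 checksums;
    re-running with the same seeds reproduces the checksums exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    # Fixture A — the 4-actor worked example
    st = fixture_a_state()
    panel = NetworkPanel(["w1"], st.x[None, :, :],
                         [f"a{k}" for k in range(1, 5)])
    table = ActorTable(pd.DataFrame(
        {"v": list(FIXTURE_A_V)},
        index=pd.Index(panel.actor_ids, name="actor_id")))
    behavior = BehaviorPanel("z", np.asarray(FIXTURE_A_Z)[None, :])
    man = write_panel(out, panel, table, {"z": behavior},
                      prefix="fixture_a")
    written.extend(man.values())

    # recovery panel with ground-truth sidecar
    cfg = recovery_config()
    panel, table, behavior, schedule, truth = generate_school(cfg)
    man = write_panel(out, panel, table, {cfg.behavior_name: behavior},
                      schedule, prefix="recovery")
    written.extend(man.values())
    gt_path = out / "recovery_truth.json"
    gt_path.write_text(json.dumps({
        "true_parameters": cfg.true_parameters,
        "rate_network": cfg.rate_network,
        "rate_behavior": cfg.rate_behavior,
        "seed": cfg.seed,
    }, indent=1, sort_keys=True))
    written.append(gt_path)

    # two-school series panel
    for name, preset, n, seed in (("sun", "homogeneous", 110, 11),
                                  ("jeff", "heterogeneous", 160, 12)):
        cfg = SchoolConfig(n_actors=n, race_preset=preset, name=name,
                           seed=seed)
        panel, table, behavior, schedule, truth = generate_school(cfg)
        man = write_panel(out, panel, table,
                          {cfg.behavior_name: behavior}, schedule,
                          prefix=name)
        written.extend(man.values())
        gp = out / f"{name}_truth.json"
        gp.write_text(json.dumps({
            "true_parameters": cfg.true_parameters,
            "seed": cfg.seed}, indent=1, sort_keys=True))
        written.append(gp)

    manifest = {p.name: _sha256(p) for p in written}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
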