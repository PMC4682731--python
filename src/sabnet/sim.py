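"""Continuous-time micro-step simulation of network-behavior co-evolution.

Between two observation waves, change unfolds as a sequence of
micro-steps: waiting times are exponential with total intensity
(number of active actors) x (sum of rates); at each event one active
actor gets an opportunity on one dependent variable (network or
behavior), chosen proportional to the rates.  A network opportunity is
a multinomial-logit choice among toggling the tie to each other active
actor or leaving the network unchanged (the no-change alternative has
gain 0); a behavior opportunity chooses among the feasible one-level
moves {-1, 0, +1}.  Each period is normalized to unit length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .effects import (EffectSpec, ModelSpec, StateView,
                      behavior_gain_vector, tie_gain_vector)
from .panel import BehaviorPanel, CompositionSchedule, NetworkPanel


@dataclass
class RateSchedule:
    """Expected change opportunities per active actor, per period.

    One entry per period for the network and for the modeled behavior.
    """

    network: np.ndarray
    behavior: np.ndarray

    def __post_init__(self) -> None:
        self.network = np.atleast_1d(np.asarray(self.network, dtype=float))
        self.behavior = np.atleast_1d(np.asarray(self.behavior, dtype=float))
        if self.network.shape != self.behavior.shape:
            raise ValueError("rate arrays must align per period")
        if (self.network < 0).any() or (self.behavior < 0).any():
            raise ValueError("rates must be nonnegative")

    @property
    def n_periods(self) -> int:
        return self.network.shape[0]


@dataclass
class MicroStep:
    time: float
    actor: int
    variable: str  # "network" | behavior name
    detail: tuple  # (j, old, new) for ties; (old, new) for behavior


@dataclass
class SimResult:
    end_state: StateView
    micro_steps: list[MicroStep] = field(default_factory=list)
    seed: int | None = None

    @property
    def n_steps(self) -> int:
        return len(self.micro_steps)


def _softmax_choice(rng: np.random.Generator, gains: np.ndarray) -> int:
    """Multinomial-logit draw; -inf entries are never chosen."""
    c = np.cumsum(np.exp(gains - gains.max()))
    return int(np.searchsorted(c, rng.random() * c[-1], side="right"))


def simulate_period(
    start: StateView,
    rates,
    model: ModelSpec | Sequence[EffectSpec],
    schedule: CompositionSchedule | None = None,
    seed: int | None = None,
    period: int = 0,
    rng: np.random.Generator | None = None,
    keep_log: bool = False,
    z_lo: int = 1,
    z_hi: int = 6,
) -> SimResult:
    """Simulate one observation period of joint micro-step dynamics.

    ``rates`` is either a :class:`RateSchedule` (indexed by ``period``)
    or a ``(network_rate, behavior_rate)`` pair.  Identical seeds give
    identical trajectories.
    """
    effects = model.effects if isinstance(model, ModelSpec) else list(model)
    if isinstance(rates, RateSchedule):
        r_net = float(rates.network[period])
        r_beh = float(rates.behavior[period])
    else:
        r_net, r_beh = (float(r) for r in rates)
    if r_net < 0 or r_beh < 0:
        raise ValueError("rates must be nonnegative")
    if rng is None:
        rng = np.random.default_rng(seed)

    state = start.copy()
    n = state.n
    if schedule is None:
        schedule = CompositionSchedule.always_present(n, 2)
    beh_name = model.behavior if isinstance(model, ModelSpec) else "z"

    # joiners enter with empty tie rows; clear any stray ties of actors
    # not yet present at the period start
    pre_active = schedule.active_at(float(period))
    state.x[~pre_active, :] = 0
    state.x[:, ~pre_active] = 0

    steps: list[MicroStep] = []
    r_tot = r_net + r_beh
    # activity is piecewise constant; recompute only past a boundary
    bounds = np.unique(np.concatenate([schedule.joins, schedule.leaves]))
    bounds = bounds[(bounds > period) & (bounds < period + 1)] - period
    net_effects = [e for e in effects
                   if e.target == "network" and e.parameter != 0.0]
    beh_effects = [e for e in effects
                   if e.target == "behavior" and e.parameter != 0.0]
    t = 0.0
    next_bound = 0
    active = schedule.active_at(float(period))
    active_idx = np.flatnonzero(active)
    state.active = active
    gains_buf = np.empty(n + 1)
    gains_buf[n] = 0.0  # the formal no-change alternative
    while r_tot > 0:
        n_act = active_idx.size
        if n_act == 0:
            break
        t += rng.exponential(1.0 / (n_act * r_tot))
        if t >= 1.0:
            break
        while next_bound < bounds.size and t >= bounds[next_bound]:
            next_bound += 1
            active = schedule.active_at(period + t)
            active_idx = np.flatnonzero(active)
            state.active = active
        if active_idx.size == 0:
            continue
        i = int(active_idx[rng.integers(active_idx.size)])
        if rng.random() < (r_net / r_tot):
            gains_buf[:n] = tie_gain_vector(net_effects, state, i)
            choice = _softmax_choice(rng, gains_buf)
            if choice < n:  # else: no change
                old = int(state.x[i, choice])
                state.x[i, choice] = 1 - old
                if keep_log:
                    steps.append(MicroStep(period + t, i, "network",
                                           (choice, old, 1 - old)))
        else:
            zi = state.z[i]
            deltas = [d for d in (-1, 0, 1) if z_lo <= zi + d <= z_hi]
            gains = behavior_gain_vector(beh_effects, state, i, deltas)
            d = deltas[_softmax_choice(rng, gains)]
            if d != 0:
                state.z[i] = zi + d
                if keep_log:
                    steps.append(MicroStep(period + t, i, beh_name,
                                           (zi, zi + d)))
    state.active = schedule.active_at(float(period + 1) - 1e-9)
    return SimResult(state, steps, seed)


def forward_simulate_panel(
    initial: StateView,
    rates: RateSchedule,
    model: ModelSpec,
    waves: int,
    seed: int | None = None,
    schedule: CompositionSchedule | None = None,
    actor_ids: Sequence[str] | None = None,
) -> tuple[NetworkPanel, BehaviorPanel]:
    """Chain :func:`simulate_period` across periods into a full panel.

    Wave 1 is the initial state; wave m+1 is the simulated end of period
    m.  With all rates zero every wave equals the first.
    """
    if waves < 2:
        raise ValueError("need at least two waves")
    if rates.n_periods not in (1, waves - 1):
        raise ValueError("rate schedule does not cover the periods")
    n = initial.n
    if schedule is None:
        schedule = CompositionSchedule.always_present(n, waves)
    if actor_ids is None:
        actor_ids = [f"a{k + 1}" for k in range(n)]
    rng = np.random.default_rng(seed)

    adjacency = np.zeros((waves, n, n), dtype=np.int8)
    scores = np.zeros((waves, n))
    state = initial
    adjacency[0] = state.x
    scores[0] = state.z
    for m in range(waves - 1):
        p = m if rates.n_periods > 1 else 0
        res = simulate_period(state, (rates.network[p], rates.behavior[p]),
                              model, schedule, period=m, rng=rng)
        state = res.end_state
        adjacency[m + 1] = state.x
        scores[m + 1] = state.z
    panel = NetworkPanel([f"w{m + 1}" for m in range(waves)], adjacency,
                         list(actor_ids))
    behavior = BehaviorPanel(model.behavior, scores)
    return panel, behavior
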