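"""Method-of-moments estimation by Robbins-Monro stochastic approximation.

Parameters are chosen so that the expected statistics of panels
simulated from the model match their observed values.  Estimation runs
in three phases: (1) a derivative matrix D of expected simulated
statistics with respect to the parameters, by finite differences with
common random numbers; (2) Robbins-Monro iteration
theta <- theta - a_t D^-1 (S_sim - S_obs) with geometrically decreasing
gains over subphases, Polyak-averaged; (3) at the final theta, many
simulations give the statistic covariance Sigma, the convergence
t-ratios mean(S_sim - S_obs)/sd(S_sim), and standard errors from
D^-1 Sigma D^-T.  Rate parameters (one per group, period and dependent
variable, on the log scale) are estimated jointly, targeting the
observed change counts; effect parameters may be pooled across groups
(multigroup estimation).

Missing data: simulation starts from the observed wave with missing
cells carried forward from the last observation (zero at the first
wave); behavior is imputed the same way.  All target statistics are
masked to the observed cells/actors at the end of each period, and the
identical mask is applied to the simulated end states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sstats

from .effects import ModelSpec, StateView, statistic_per_actor
from .panel import (MISSING, PRESENT, ActorTable, BehaviorPanel,
                    CompositionSchedule, NetworkPanel)
from .sim import simulate_period


# ---------------------------------------------------------------------------
# data preparation

def _impute_adjacency(panel: NetworkPanel) -> np.ndarray:
    """Last-observation-carried-forward adjacency; first-wave missing -> 0."""
    adj = panel.adjacency
    out = np.zeros_like(adj)
    out[0] = np.where(adj[0] == MISSING, 0, adj[0])
    for w in range(1, panel.n_waves):
        out[w] = np.where(adj[w] == MISSING, out[w - 1], adj[w])
    return out


def _impute_behavior(bp: BehaviorPanel) -> np.ndarray:
    """LOCF behavior; leading missing backfilled; never-observed -> median."""
    z = bp.scores.copy()
    n_waves, n = z.shape
    obs_any = ~np.all(np.isnan(z), axis=0)
    fallback = float(np.round(np.nanmedian(z))) if obs_any.any() else bp.lo
    for i in range(n):
        col = z[:, i]
        if np.all(np.isnan(col)):
            z[:, i] = fallback
            continue
        first = np.flatnonzero(~np.isnan(col))[0]
        col[:first] = col[first]
        for w in range(first + 1, n_waves):
            if np.isnan(col[w]):
                col[w] = col[w - 1]
    return z


def _covariate_arrays(table: ActorTable | None, model: ModelSpec,
                      n: int, wave: int) -> dict[str, np.ndarray]:
    """Covariates referenced by the model, imputed at the column mean."""
    need = {e.covariate for e in model.effects
            if e.covariate not in (None, model.behavior, "z")}
    out: dict[str, np.ndarray] = {}
    for name in need:
        if table is None or not table.has(name):
            raise KeyError(f"covariate {name!r} not available")
        try:
            v = table.column(name, wave=wave)
        except KeyError:
            v = table.column(name)
        v = np.asarray(v, dtype=float)
        if np.isnan(v).any():
            fill = np.nanmean(v) if not np.all(np.isnan(v)) else 0.0
            v = np.where(np.isnan(v), fill, v)
        out[name] = v
    return out


@dataclass
class GroupData:
    """One school's panel, prepared for simulation-based estimation."""

    panel: NetworkPanel
    behavior: BehaviorPanel
    table: ActorTable | None = None
    schedule: CompositionSchedule | None = None
    name: str = "group"

    def __post_init__(self) -> None:
        n, W = self.panel.n_actors, self.panel.n_waves
        if self.behavior.scores.shape != (W, n):
            raise ValueError("behavior panel does not match network panel")
        if self.schedule is None:
            self.schedule = CompositionSchedule.always_present(n, W)
        for w in range(W):
            if not self.panel.respondent_mask(w).any():
                raise ValueError(
                    f"{self.name}: wave {self.panel.waves[w]} is entirely "
                    "missing")
        self.x_imp = _impute_adjacency(self.panel)
        self.z_imp = _impute_behavior(self.behavior)

    @property
    def n_periods(self) -> int:
        return self.panel.n_waves - 1


@dataclass
class TargetStatistics:
    """Observed moment targets: one entry per free parameter."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.labels) != self.values.size:
            raise ValueError("labels/values mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("targets must be finite")


class _Moments:
    """Computes the moment vector for observed or simulated end states."""

    def __init__(self, groups: Sequence[GroupData], model: ModelSpec):
        self.groups = list(groups)
        self.model = model
        self.free = model.free_effects
        if not self.free:
            raise ValueError("model has no free effects")
        self.means = self._centering_means()
        self._masks = [self._group_masks(g) for g in self.groups]

    # -- centering pooled over groups and waves
    def _centering_means(self) -> dict[str, float]:
        means: dict[str, float] = {}
        if self.model.center_behavior:
            allz = np.concatenate(
                [g.behavior.scores.ravel() for g in self.groups])
            means[self.model.behavior] = float(np.nanmean(allz))
        if self.model.center_covariates:
            need = {e.covariate for e in self.model.effects
                    if e.covariate not in (None, self.model.behavior, "z")}
            for name in need:
                vals = []
                for g in self.groups:
                    if g.table is not None and g.table.has(name):
                        try:
                            vals.append(g.table.column(name))
                        except KeyError:
                            vals.append(g.table.column(name, wave=0))
                if vals:
                    means[name] = float(np.nanmean(np.concatenate(vals)))
        return means

    def _group_masks(self, g: GroupData) -> list[dict]:
        out = []
        n = g.panel.n_actors
        off = ~np.eye(n, dtype=bool)
        for m in range(g.n_periods):
            a0, a1 = g.panel.adjacency[m], g.panel.adjacency[m + 1]
            active_end = g.schedule.active_at(float(m + 1))
            out.append({
                "cell_end": (a1 != MISSING) & off,
                "cell_joint": (a0 != MISSING) & (a1 != MISSING) & off,
                "net_actors": g.panel.respondent_mask(m + 1) & active_end,
                "beh_end": g.behavior.observed(m + 1) & active_end,
                "beh_joint": (g.behavior.observed(m)
                              & g.behavior.observed(m + 1) & active_end),
                "active_end": active_end,
            })
        return out

    @property
    def labels(self) -> list[str]:
        labs = []
        for gi, g in enumerate(self.groups):
            for m in range(g.n_periods):
                labs.append(f"rate:net:{g.name}:p{m + 1}")
                labs.append(f"rate:beh:{g.name}:p{m + 1}")
        labs.extend(e.key for e in self.free)
        return labs

    @property
    def n_rates(self) -> int:
        return 2 * sum(g.n_periods for g in self.groups)

    @property
    def n_params(self) -> int:
        return self.n_rates + len(self.free)

    def start_state(self, gi: int, m: int) -> StateView:
        g = self.groups[gi]
        cov = _covariate_arrays(g.table, self.model, g.panel.n_actors, m)
        return StateView(
            x=g.x_imp[m].copy(), z=g.z_imp[m].copy(), covariates=cov,
            active=g.schedule.active_at(float(m)),
            z_name=self.model.behavior, means=self.means)

    def period_stats(self, gi: int, m: int, x_end: np.ndarray,
                     z_end: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(rate pair, effect statistics) for one period's end state.

        ``x_end`` is a 0/1 adjacency and ``z_end`` a fully-imputed score
        vector; the observed-data missingness masks are applied here so
        observed and simulated end states are treated identically.
        """
        g = self.groups[gi]
        msk = self._masks[gi][m]
        x_start = g.x_imp[m]
        x_end_m = np.where(msk["cell_end"], x_end, 0).astype(np.int8)
        rate_net = float(
            (x_end[msk["cell_joint"]] != x_start[msk["cell_joint"]]).sum())
        bj = msk["beh_joint"]
        rate_beh = float(np.abs(z_end[bj] - g.z_imp[m][bj]).sum())

        cov = _covariate_arrays(g.table, self.model, g.panel.n_actors, m)
        base = StateView(x_end_m, z_end, cov, msk["active_end"],
                         self.model.behavior, self.means)
        x_new = ((x_start == 0) & (x_end_m == 1)).astype(np.int8)
        x_old = ((x_start == 1) & (x_end_m == 1)).astype(np.int8)
        vals = np.empty(len(self.free))
        for k, eff in enumerate(self.free):
            if eff.target == "network":
                if eff.role == "creation":
                    st = StateView(x_new, z_end, cov, msk["active_end"],
                                   self.model.behavior, self.means)
                elif eff.role == "endowment":
                    st = StateView(x_old, z_end, cov, msk["active_end"],
                                   self.model.behavior, self.means)
                else:
                    st = base
                amask = msk["net_actors"]
            else:
                st = base
                amask = msk["beh_end"]
            per_actor = statistic_per_actor(eff, st)
            vals[k] = float(per_actor[amask & st.active].sum())
        return np.array([rate_net, rate_beh]), vals

    def observed(self) -> TargetStatistics:
        rates, effs = [], np.zeros(len(self.free))
        for gi, g in enumerate(self.groups):
            for m in range(g.n_periods):
                x_end = (g.panel.adjacency[m + 1] == PRESENT).astype(np.int8)
                r, v = self.period_stats(gi, m, x_end, g.z_imp[m + 1])
                rates.extend(r)
                effs += v
        return TargetStatistics(self.labels,
                                np.concatenate([rates, effs]))

    def simulate(self, log_rates: np.ndarray, theta: np.ndarray,
                 seed_entropy: tuple) -> np.ndarray:
        """One simulated moment vector at the given parameters."""
        model = self.model.with_parameters(theta)
        rates = np.exp(log_rates).reshape(-1, 2)
        ridx = 0
        out_rates, out_effs = [], np.zeros(len(self.free))
        for gi, g in enumerate(self.groups):
            for m in range(g.n_periods):
                r_net, r_beh = rates[ridx]
                ridx += 1
                start = self.start_state(gi, m)
                rng = np.random.default_rng(
                    np.random.SeedSequence(list(seed_entropy) + [gi, m]))
                res = simulate_period(
                    start, (r_net, r_beh), model, g.schedule, period=m,
                    rng=rng, z_lo=g.behavior.lo, z_hi=g.behavior.hi)
                r, v = self.period_stats(
                    gi, m, res.end_state.x, res.end_state.z)
                out_rates.extend(r)
                out_effs += v
        return np.concatenate([out_rates, out_effs])


def observed_targets(panel: NetworkPanel, behavior: BehaviorPanel,
                     model: ModelSpec, table: ActorTable | None = None,
                     schedule: CompositionSchedule | None = None
                     ) -> TargetStatistics:
    """Observed moment targets for a single-group model."""
    mom = _Moments([GroupData(panel, behavior, table, schedule)], model)
    return mom.observed()


# ---------------------------------------------------------------------------
# fitting

@dataclass
class FitOptions:
    """Operating points of the stochastic-approximation fit.

    All counts trade Monte-Carlo noise for runtime; the defaults are
    conventional operating points for desk-scale panels.
    """

    n_phase1: int = 30
    n_phase2_subphases: int = 4
    n_phase2_iter: int = 30
    phase3_iterations: int = 500
    gain0: float = 0.2
    fd_step: float = 0.4
    conv_threshold: float = 0.15
    max_reruns: int = 3
    seed: int = 0
    theta_clip: float = 6.0
    max_step: float = 0.3
    rate_lo: float = 0.02
    rate_hi: float = 40.0


@dataclass
class EstimationResult:
    """Fitted parameters with uncertainty and convergence diagnostics."""

    effect_keys: list[str]
    theta: np.ndarray
    se: np.ndarray
    rate_labels: list[str]
    rates: np.ndarray
    rate_se: np.ndarray
    conv_t: np.ndarray  # per target statistic (rates then effects)
    labels: list[str]
    converged: bool
    n_iterations: int
    seed: int
    n_reruns: int = 0
    model: ModelSpec | None = None

    @property
    def max_conv_t(self) -> float:
        return float(np.nanmax(np.abs(self.conv_t)))

    def pvalues(self) -> np.ndarray:
        z = np.divide(self.theta, self.se,
                      out=np.full_like(self.theta, np.nan),
                      where=self.se > 0)
        return 2.0 * sstats.norm.sf(np.abs(z))

    def stars(self) -> list[str]:
        out = []
        for p in self.pvalues():
            out.append("***" if p < 0.001 else "**" if p < 0.01
                       else "*" if p < 0.05 else "")
        return out

    def to_frame(self):
        import pandas as pd
        eff_t = self.conv_t[len(self.rate_labels):]
        rows = [{"parameter": k, "b": t, "se": s, "sig": st, "conv_t": c}
                for k, t, s, st, c in zip(self.effect_keys, self.theta,
                                          self.se, self.stars(), eff_t)]
        for k, r, s, c in zip(self.rate_labels, self.rates, self.rate_se,
                              self.conv_t[:len(self.rate_labels)]):
            rows.append({"parameter": k, "b": r, "se": s, "sig": "",
                         "conv_t": c})
        return pd.DataFrame(rows)

    def get(self, key_fragment: str) -> tuple[float, float]:
        """(estimate, se) for the unique effect whose key contains
        ``key_fragment``."""
        hits = [k for k, lab in enumerate(self.effect_keys)
                if key_fragment in lab]
        if len(hits) != 1:
            raise KeyError(f"{key_fragment!r} matches {len(hits)} effects")
        return float(self.theta[hits[0]]), float(self.se[hits[0]])


def _initial_params(mom: _Moments, s_obs: np.ndarray,
                    opts: FitOptions) -> tuple[np.ndarray, np.ndarray]:
    """Rates from observed change counts; outdegree -1, others initial."""
    log_rates = []
    ridx = 0
    for g in mom.groups:
        active_n = max(int(g.schedule.active_at(0.0).sum()), 1)
        for m in range(g.n_periods):
            for _ in range(2):
                c = s_obs[ridx]
                ridx += 1
                r0 = np.clip(1.3 * c / active_n + 0.1, opts.rate_lo,
                             opts.rate_hi)
                log_rates.append(np.log(r0))
    theta = []
    for e in mom.free:
        if e.initial != 0.0:
            theta.append(e.initial)
        elif e.parameter != 0.0:
            theta.append(e.parameter)  # warm start from current values
        elif e.name == "outdegree" and e.target == "network":
            theta.append(-1.0)
        else:
            theta.append(0.0)
    return np.array(log_rates), np.array(theta)


def _estimate_derivative(mom: _Moments, log_rates: np.ndarray,
                         theta: np.ndarray, opts: FitOptions,
                         entropy_tag: int, n_reps: int) -> np.ndarray:
    """Finite-difference derivative of E[S] with common random numbers."""
    p_r, p_t = log_rates.size, theta.size
    P = p_r + p_t
    D = np.zeros((P, P))
    eps = opts.fd_step
    base = np.stack([
        mom.simulate(log_rates, theta, (opts.seed, entropy_tag, r))
        for r in range(n_reps)])
    for k in range(P):
        lr, th = log_rates.copy(), theta.copy()
        if k < p_r:
            lr[k] += eps
        else:
            th[k - p_r] += eps
        pert = np.stack([
            mom.simulate(lr, th, (opts.seed, entropy_tag, r))
            for r in range(n_reps)])
        D[:, k] = (pert - base).mean(axis=0) / eps
    return D


def _solve(D: np.ndarray, dev: np.ndarray, rel_floor: float = 1e-2
           ) -> np.ndarray:
    """Newton step with small singular values floored.

    The derivative matrix is a Monte-Carlo estimate; flooring its
    spectrum keeps steps in weakly-identified directions bounded
    instead of letting noise blow them up.
    """
    try:
        U, s, Vt = np.linalg.svd(D)
    except np.linalg.LinAlgError:  # pragma: no cover
        raise np.linalg.LinAlgError(
            "derivative matrix is degenerate; the model is likely "
            "unidentified — consider removing an effect")
    if s[0] <= 0 or not np.all(np.isfinite(s)):
        raise np.linalg.LinAlgError(
            "derivative matrix is (near-)singular; the model is likely "
            "unidentified — consider removing an effect")
    s = np.maximum(s, rel_floor * s[0])
    return Vt.T @ ((U.T @ dev) / s)


def fit_groups(groups: Sequence[GroupData], model: ModelSpec,
               options: FitOptions | None = None) -> EstimationResult:
    """Method-of-moments fit, single- or multi-group.

    Effect parameters are pooled across groups; rate parameters are per
    group and period.  The result is flagged (``converged=False``) when
    the largest absolute convergence t-ratio stays above the threshold
    after the allowed re-runs.
    """
    opts = options or FitOptions()
    mom = _Moments(groups, model)
    targets = mom.observed()
    s_obs = targets.values
    if np.all(s_obs[:mom.n_rates] == 0):
        raise ValueError("no observed change between waves; nothing to fit")
    log_rates, theta = _initial_params(mom, s_obs, opts)
    p_r = log_rates.size
    lo, hi = np.log(opts.rate_lo), np.log(opts.rate_hi)

    n_iter_total = 0
    rerun = 0
    while True:
        # phase 1: derivative at the current parameters
        D = _estimate_derivative(mom, log_rates, theta, opts,
                                 entropy_tag=100 + rerun,
                                 n_reps=opts.n_phase1)
        # phase 2: Robbins-Monro with decreasing gains
        it_seed = 0
        for sub in range(opts.n_phase2_subphases):
            a = opts.gain0 / (2.0 ** sub)
            n_iter = int(np.ceil(opts.n_phase2_iter * 1.5 ** sub))
            acc_lr = np.zeros_like(log_rates)
            acc_th = np.zeros_like(theta)
            for it in range(n_iter):
                s_sim = mom.simulate(
                    log_rates, theta,
                    (opts.seed, 200 + rerun, sub, it_seed))
                it_seed += 1
                n_iter_total += 1
                step = _solve(D, s_sim - s_obs)
                step = np.clip(a * step, -opts.max_step, opts.max_step)
                log_rates = np.clip(log_rates - step[:p_r], lo, hi)
                theta = np.clip(theta - step[p_r:], -opts.theta_clip,
                                opts.theta_clip)
                acc_lr += log_rates
                acc_th += theta
            log_rates = acc_lr / n_iter
            theta = acc_th / n_iter

        # phase 3: diagnostics at fixed theta-hat
        D = _estimate_derivative(mom, log_rates, theta, opts,
                                 entropy_tag=300 + rerun,
                                 n_reps=opts.n_phase1)
        sims = np.stack([
            mom.simulate(log_rates, theta, (opts.seed, 400 + rerun, r))
            for r in range(opts.phase3_iterations)])
        dev_mean = sims.mean(axis=0) - s_obs
        sd = sims.std(axis=0, ddof=1)
        conv_t = np.divide(dev_mean, sd,
                           out=np.where(dev_mean == 0, 0.0, np.inf),
                           where=sd > 0)
        max_t = float(np.nanmax(np.abs(conv_t)))
        ok = max_t <= opts.conv_threshold
        if ok or rerun >= opts.max_reruns:
            break
        if rerun >= 1 and max_t > 0.5:
            # a warm re-run stayed far off: likely a wrong basin of the
            # moment equations — restart cold instead of polishing it
            log_rates, theta = _initial_params(mom, s_obs, opts)
        rerun += 1

    sigma = np.cov(sims.T) if sims.shape[0] > 1 else np.zeros((len(s_obs),) * 2)
    try:
        U, sv, Vt = np.linalg.svd(D)
        sv = np.maximum(sv, 1e-6 * sv[0])  # guard exact singularity only
        Dinv = Vt.T @ (U.T / sv[:, None])
        covm = Dinv @ sigma @ Dinv.T
        se_all = np.sqrt(np.clip(np.diag(covm), 0.0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        warnings.warn("singular derivative matrix in phase 3; no se")
        se_all = np.full(len(s_obs), np.nan)

    rates = np.exp(log_rates)
    rate_se = se_all[:p_r] * rates  # delta method from the log scale
    if not ok:
        warnings.warn(
            f"fit did not converge: max |conv t| = "
            f"{float(np.nanmax(np.abs(conv_t))):.3f} after {rerun} re-runs")
    return EstimationResult(
        effect_keys=[e.key for e in mom.free],
        theta=theta.copy(), se=se_all[p_r:],
        rate_labels=targets.labels[:p_r], rates=rates, rate_se=rate_se,
        conv_t=conv_t, labels=targets.labels, converged=bool(ok),
        n_iterations=n_iter_total, seed=opts.seed, n_reruns=rerun,
        model=mom.model.with_parameters(theta))


def fit(panel: NetworkPanel, behavior: BehaviorPanel, model: ModelSpec,
        table: ActorTable | None = None,
        schedule: CompositionSchedule | None = None,
        options: FitOptions | None = None) -> EstimationResult:
    """Single-group method-of-moments fit."""
    return fit_groups([GroupData(panel, behavior, table, schedule)],
                      model, options)


@dataclass
class MultigroupSpec:
    """Joint estimation across groups with pooled effect parameters."""

    groups: list[GroupData]
    model: ModelSpec

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("multigroup estimation needs >= 2 groups")


def fit_multigroup(spec: MultigroupSpec,
                   options: FitOptions | None = None) -> EstimationResult:
    """Pooled fit: one theta for shared effects, per-group rates."""
    return fit_groups(spec.groups, spec.model, options)
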