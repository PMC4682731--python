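"""The model-series driver: a ladder of nested co-evolution models.

The series mirrors the standard reporting layout for joint
selection/influence analyses of drinking and friendship:

* M1 — selection only: ego, alter and ego x alter drinking terms over a
  structural baseline (outdegree, reciprocity); behavior evolves under
  shape effects alone.
* M2 — influence only: average alter over the shape effects; network
  evolves under the structural baseline alone.
* M3 — selection with the ego x alter term split into new-tie formation
  (creation role) and existing-tie continuation (endowment role).
* M4 — M3 plus average-alter influence (the joint model).
* M5 — M4 plus network closure controls (transitive triplets, 3-cycles,
  indegree popularity sqrt) and indegree/outdegree influence terms.
* M6 — M5 plus covariate effects.

For two groups the driver fits each school separately, fits the pooled
multigroup model (the "Both" column), and reports the between-group
t-ratio per effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effects import EffectSpec, ModelSpec
from .mom import (EstimationResult, FitOptions, GroupData, MultigroupSpec,
                  fit_groups, fit_multigroup)

MODEL_IDS = ("M1", "M2", "M3", "M4", "M5", "M6")


def odds_ratio(b: float) -> float:
    """Odds-ratio interpretation of a logit coefficient: exp(b)."""
    if not math.isfinite(b):
        raise ValueError("coefficient must be finite")
    return math.exp(b)


def t_diff(b1: float, se1: float, b2: float, se2: float) -> float:
    """Two-group coefficient comparison (b1 - b2)/sqrt(se1^2 + se2^2)."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    return (b1 - b2) / math.sqrt(se1 ** 2 + se2 ** 2)


def significance_stars(b: float, se: float) -> str:
    """Two-sided normal stars at 0.05 / 0.01 / 0.001."""
    from scipy.stats import norm
    if se <= 0 or not math.isfinite(b):
        return ""
    p = 2 * norm.sf(abs(b) / se)
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 \
        else ""


@dataclass
class SeriesConfig:
    """Which behavior, which models, and the covariate sets for M6."""

    behavior: str = "alcohol"
    models: tuple[str, ...] = MODEL_IDS
    same_covariates: tuple[str, ...] = ("sex", "race")
    behavior_covariates: tuple[str, ...] = ("sex", "parent_drinking",
                                            "alcohol_easy")
    center_behavior: bool = True

    def __post_init__(self) -> None:
        bad = set(self.models) - set(MODEL_IDS)
        if bad:
            raise ValueError(f"unknown model ids: {sorted(bad)}")


def build_model(model_id: str, config: SeriesConfig) -> ModelSpec:
    """Effect list for one rung of the ladder."""
    var = config.behavior
    E = EffectSpec
    structural = [E("outdegree"), E("reciprocity")]
    closure = [E("transitive_triplets"), E("three_cycles"),
               E("indegree_popularity_sqrt")]
    sel_main = [E("ego", covariate=var), E("alter", covariate=var)]
    sel_eval = [E("ego_x_alter", covariate=var)]
    sel_split = [E("ego_x_alter", covariate=var, role="creation"),
                 E("ego_x_alter", covariate=var, role="endowment")]
    shapes = [E("linear", target="behavior"),
              E("quadratic", target="behavior")]
    influence = [E("average_alter", target="behavior")]
    inout = [E("indegree", target="behavior"),
             E("outdegree", target="behavior")]

    if model_id == "M1":
        effects = structural + sel_main + sel_eval + shapes
    elif model_id == "M2":
        effects = structural + shapes + influence
    elif model_id == "M3":
        effects = structural + sel_main + sel_split + shapes
    elif model_id == "M4":
        effects = structural + sel_main + sel_split + shapes + influence
    elif model_id == "M5":
        effects = (structural + closure + sel_main + sel_split + shapes
                   + inout + influence)
    elif model_id == "M6":
        effects = (structural + closure + sel_main + sel_split
                   + [E("same", covariate=c) for c in config.same_covariates]
                   + shapes + inout + influence
                   + [E("covariate", target="behavior", covariate=c)
                      for c in config.behavior_covariates])
    else:
        raise ValueError(f"unknown model id {model_id!r}")
    return ModelSpec(var, effects, center_behavior=config.center_behavior)


@dataclass
class SeriesResult:
    table: pd.DataFrame
    fits: dict[tuple[str, str], EstimationResult | None]
    metadata: dict = field(default_factory=dict)


def _fit_or_none(groups, model, options, label, notes):
    try:
        return fit_groups(groups, model, options)
    except Exception as exc:  # noqa: BLE001 — annotate rather than abort
        notes.append(f"{label}: {type(exc).__name__}: {exc}")
        return None


def run_series(groups: list[GroupData], config: SeriesConfig,
               options: FitOptions | None = None) -> SeriesResult:
    """Fit the requested model ladder for one or two schools.

    With two groups each model is fit per school and pooled; the table
    has one row per (model, effect) with per-group coefficients and the
    between-school t-ratio.  Failed fits leave NaN cells and a note in
    the metadata instead of aborting the series.
    """
    if not 1 <= len(groups) <= 2:
        raise ValueError("run_series expects one or two groups")
    options = options or FitOptions()
    notes: list[str] = []
    fits: dict[tuple[str, str], EstimationResult | None] = {}
    rows = []
    for mid in config.models:
        model = build_model(mid, config)
        per_group = {}
        for g in groups:
            opts = FitOptions(**{**options.__dict__})
            res = _fit_or_none([g], model, opts, f"{mid}/{g.name}", notes)
            per_group[g.name] = res
            fits[(mid, g.name)] = res
        pooled = None
        if len(groups) == 2:
            pooled = _fit_or_none(groups, model, options, f"{mid}/both",
                                  notes)
            fits[(mid, "both")] = pooled

        keys = [e.key for e in model.free_effects]
        for key in keys:
            row: dict = {"model": mid, "parameter": key}
            if pooled is not None:
                b, s = pooled.get(key)
                row.update(both_b=b, both_se=s,
                           both_sig=significance_stars(b, s))
            for g in groups:
                res = per_group[g.name]
                if res is None:
                    row.update({f"{g.name}_b": np.nan,
                                f"{g.name}_se": np.nan})
                    continue
                b, s = res.get(key)
                row.update({f"{g.name}_b": b, f"{g.name}_se": s,
                            f"{g.name}_sig": significance_stars(b, s)})
            if len(groups) == 2:
                r1, r2 = (per_group[g.name] for g in groups)
                if r1 is not None and r2 is not None:
                    b1, s1 = r1.get(key)
                    b2, s2 = r2.get(key)
                    try:
                        row["t_diff"] = t_diff(b1, s1, b2, s2)
                    except ValueError:
                        row["t_diff"] = np.nan
                else:
                    row["t_diff"] = np.nan
            rows.append(row)

    meta = {
        "seed": options.seed,
        "behavior": config.behavior,
        "models": list(config.models),
        "notes": notes,
        "convergence": {
            f"{mid}/{gname}": (None if res is None
                               else {"converged": res.converged,
                                     "max_conv_t": res.max_conv_t})
            for (mid, gname), res in fits.items()},
    }
    return SeriesResult(pd.DataFrame(rows), fits, meta)
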