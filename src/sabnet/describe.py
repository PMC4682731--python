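"""Descriptive statistics for longitudinal friendship panels.

Covers the standard reporting battery for actor-oriented analyses:
density and average degree (with both the all-actor and the
respondent-only denominator, since nonresponse makes the choice
material), dyad census, tie- and behavior-change tables between waves,
the Jaccard tie-stability index, network autocorrelation (Moran's I) at
geodesic distances 1 and 2, and the friend-similarity index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, PRESENT, BehaviorPanel, NetworkPanel


@dataclass(frozen=True)
class DyadCensus:
    mutual: int
    asymmetric: int
    null: int

    @property
    def total(self) -> int:
        return self.mutual + self.asymmetric + self.null


@dataclass(frozen=True)
class ChangeTable:
    """Tie transitions between two waves over jointly-observed cells."""

    created: int  # 0 -> 1
    dissolved: int  # 1 -> 0
    stable: int  # 1 -> 1


def dyad_census(adj: np.ndarray) -> DyadCensus:
    """Partition unordered non-missing dyads into mutual/asymmetric/null."""
    adj = np.asarray(adj)
    n = adj.shape[0]
    if adj.shape != (n, n):
        raise ValueError("adjacency must be square")
    if np.any(np.diagonal(adj) == PRESENT):
        raise ValueError("self-ties are not allowed")
    iu, ju = np.triu_indices(n, k=1)
    a, b = adj[iu, ju], adj[ju, iu]
    ok = (a != MISSING) & (b != MISSING)
    s = a[ok] + b[ok]
    return DyadCensus(int((s == 2).sum()), int((s == 1).sum()),
                      int((s == 0).sum()))


def tie_change_table(adj0: np.ndarray, adj1: np.ndarray) -> ChangeTable:
    """Created / dissolved / stable ties over cells observed at both waves."""
    adj0, adj1 = np.asarray(adj0), np.asarray(adj1)
    n = adj0.shape[0]
    off = ~np.eye(n, dtype=bool)
    ok = (adj0 != MISSING) & (adj1 != MISSING) & off
    a0, a1 = adj0[ok], adj1[ok]
    return ChangeTable(int(((a0 == 0) & (a1 == 1)).sum()),
                       int(((a0 == 1) & (a1 == 0)).sum()),
                       int(((a0 == 1) & (a1 == 1)).sum()))


def behavior_change_table(z0: np.ndarray, z1: np.ndarray) -> dict[str, int]:
    """Increase / decrease / no-change counts over jointly-observed actors."""
    z0, z1 = np.asarray(z0, float), np.asarray(z1, float)
    ok = ~np.isnan(z0) & ~np.isnan(z1)
    return {
        "increase": int((z1[ok] > z0[ok]).sum()),
        "decrease": int((z1[ok] < z0[ok]).sum()),
        "no_change": int((z1[ok] == z0[ok]).sum()),
    }


def jaccard_stability(change: ChangeTable) -> float:
    """Fraction of stable ties among created, dissolved, and stable ones.

    The conventional index for judging whether adjacent waves carry
    enough persistence for longitudinal network modeling.  Undefined
    (NaN) when no tie was ever present in either wave.
    """
    denom = change.created + change.dissolved + change.stable
    if denom == 0:
        return float("nan")
    return change.stable / denom


def _exact_distance_weights(adj: np.ndarray, distance: int,
                            symmetrize: bool = False) -> np.ndarray:
    """Binary weights w_ij = 1 iff geodesic distance(i, j) == distance."""
    x = (np.asarray(adj) == PRESENT)
    if symmetrize:
        x = x | x.T
    n = x.shape[0]
    reached = np.eye(n, dtype=bool)
    frontier = np.eye(n, dtype=bool)
    for _ in range(distance):
        nxt = (frontier @ x) & ~reached
        reached |= nxt
        frontier = nxt
    np.fill_diagonal(frontier, False)
    return frontier.astype(float)


def morans_i(adj: np.ndarray, z: np.ndarray, distance: int = 1,
             symmetrize: bool = False, row_normalize: bool = False) -> float:
    """Network autocorrelation of attribute ``z`` at an exact geodesic
    distance (directed ties followed forward by default).

    I = (n / W) * sum_ij w_ij (z_i - zbar)(z_j - zbar) / sum_i (z_i - zbar)^2

    Returns NaN when the attribute has zero variance or no pair sits at
    the requested distance.  Actors with missing ``z`` are dropped.
    """
    z = np.asarray(z, dtype=float)
    obs = ~np.isnan(z)
    adj = np.asarray(adj)
    if not obs.all():
        adj = adj[np.ix_(obs, obs)]
        z = z[obs]
    adj = np.where(adj == MISSING, 0, adj)
    n = z.size
    if n < 2:
        return float("nan")
    w = _exact_distance_weights(adj, distance, symmetrize)
    if row_normalize:
        rs = w.sum(axis=1, keepdims=True)
        w = np.divide(w, rs, out=np.zeros_like(w), where=rs > 0)
    big_w = w.sum()
    dev = z - z.mean()
    ss = (dev ** 2).sum()
    if big_w == 0 or ss == 0:
        return float("nan")
    return float((n / big_w) * (dev @ w @ dev) / ss)


def similarity_mean(adj: np.ndarray, z: np.ndarray,
                    range_width: float = 5.0) -> float:
    """Mean friend-similarity 1 - |z_i - z_j| / range over present ties.

    1 means every friendship joins identical scores, 0 maximally
    dissimilar ones.  Ties with a missing score on either end drop out.
    """
    if range_width <= 0:
        raise ValueError("range_width must be positive")
    z = np.asarray(z, dtype=float)
    ii, jj = np.nonzero(np.asarray(adj) == PRESENT)
    zi, zj = z[ii], z[jj]
    ok = ~np.isnan(zi) & ~np.isnan(zj)
    if not ok.any():
        return float("nan")
    return float(np.mean(1.0 - np.abs(zi[ok] - zj[ok]) / range_width))


def describe_panel(
    panel: NetworkPanel,
    behaviors: dict[str, BehaviorPanel] | BehaviorPanel | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-wave and per-period descriptive tables.

    The wave table reports density and average degree under both the
    all-actor and the respondent (non-missing outgoing row) denominator,
    tie counts, missing fraction, the dyad census, and Moran's I at
    distances 1 and 2 for each behavior.  The period table reports tie
    change counts, Jaccard stability, and behavior change counts.
    """
    if isinstance(behaviors, BehaviorPanel):
        behaviors = {behaviors.variable_name: behaviors}
    behaviors = behaviors or {}
    n_all = panel.n_actors
    wave_rows = []
    for w in range(panel.n_waves):
        adj = panel.adjacency[w]
        ties = panel.tie_count(w)
        resp = panel.respondent_mask(w)
        n_eff = int(resp.sum())
        census = dyad_census(adj)
        row = {
            "wave": panel.waves[w],
            "n_actors": n_all,
            "n_respondents": n_eff,
            "ties": ties,
            "density_all": ties / (n_all * (n_all - 1)) if n_all > 1 else
            float("nan"),
            "density_obs": ties / (n_eff * (n_eff - 1)) if n_eff > 1 else
            float("nan"),
            "avg_degree_all": ties / n_all if n_all else float("nan"),
            "avg_degree_obs": ties / n_eff if n_eff else float("nan"),
            "missing_fraction": panel.missing_fraction(w),
            "mutual": census.mutual,
            "asymmetric": census.asymmetric,
            "null": census.null,
        }
        for name, bp in behaviors.items():
            z = bp.scores[w]
            row[f"morans_i_{name}"] = morans_i(adj, z, distance=1)
            row[f"morans_i_d2_{name}"] = morans_i(adj, z, distance=2)
            row[f"similarity_{name}"] = similarity_mean(adj, z)
        wave_rows.append(row)

    period_rows = []
    for m in range(panel.n_waves - 1):
        ct = tie_change_table(panel.adjacency[m], panel.adjacency[m + 1])
        row = {
            "period": f"{panel.waves[m]}->{panel.waves[m + 1]}",
            "ties_created": ct.created,
            "ties_dissolved": ct.dissolved,
            "ties_stable": ct.stable,
            "jaccard": jaccard_stability(ct),
        }
        for name, bp in behaviors.items():
            bc = behavior_change_table(bp.scores[m], bp.scores[m + 1])
            row[f"{name}_increase"] = bc["increase"]
            row[f"{name}_decrease"] = bc["decrease"]
            row[f"{name}_no_change"] = bc["no_change"]
        period_rows.append(row)
    return pd.DataFrame(wave_rows), pd.DataFrame(period_rows)
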