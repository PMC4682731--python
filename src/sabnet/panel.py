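"""Longitudinal network / behavior panel data model and CSV I/O.

The data layout mirrors a multi-wave sociometric survey: per wave a
directed friendship nomination network over a fixed actor roster, an
actor attribute table (fixed and per-wave covariates), and one or more
ordinal behavior variables observed per wave.  Cells of the adjacency
matrix are three-state: absent (0), present (1), or missing (-1).
Missingness is actor-wise by convention — a non-respondent at a wave has
their whole outgoing row missing.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: adjacency cell codes
ABSENT = 0
PRESENT = 1
MISSING = -1


@dataclass
class NetworkPanel:
    """Ordered waves of directed adjacency over a shared actor roster.

    ``adjacency`` has shape ``(n_waves, n, n)`` with int8 cells in
    {0, 1, -1}; the diagonal is structurally 0 at every wave.
    """

    waves: list[str]
    adjacency: np.ndarray
    actor_ids: list[str]

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.int8)
        n = len(self.actor_ids)
        if self.adjacency.shape != (len(self.waves), n, n):
            raise ValueError(
                f"adjacency shape {self.adjacency.shape} does not match "
                f"{len(self.waves)} waves x {n} actors"
            )
        bad = ~np.isin(self.adjacency, (ABSENT, PRESENT, MISSING))
        if bad.any():
            raise ValueError("adjacency cells must be in {0, 1, -1}")
        diag = self.adjacency[:, np.arange(n), np.arange(n)]
        if (diag != 0).any():
            raise ValueError("self-ties are structurally forbidden")
        if len(set(self.actor_ids)) != n:
            raise ValueError("actor ids must be unique")

    @property
    def n_actors(self) -> int:
        return len(self.actor_ids)

    @property
    def n_waves(self) -> int:
        return len(self.waves)

    def index_of(self, actor_id: str) -> int:
        return self.actor_ids.index(actor_id)

    def observed(self, wave: int) -> np.ndarray:
        """Boolean mask of observed (non-missing) cells at a wave."""
        return self.adjacency[wave] != MISSING

    def respondent_mask(self, wave: int) -> np.ndarray:
        """Actors whose outgoing row is (at least partly) observed."""
        n = self.n_actors
        off = ~np.eye(n, dtype=bool)
        return ((self.adjacency[wave] != MISSING) & off).any(axis=1)

    def missing_fraction(self, wave: int) -> float:
        """Fraction of actors with a fully-missing outgoing row."""
        return 1.0 - self.respondent_mask(wave).mean()

    def tie_count(self, wave: int) -> int:
        return int((self.adjacency[wave] == PRESENT).sum())


@dataclass
class ActorTable:
    """Fixed and per-wave actor covariates, one row per panel actor.

    ``data`` is indexed by actor id.  Fixed covariates are plain columns
    (``sex``, ``grade``, ``race``, ``parent_education``,
    ``parent_drinking``, ``alcohol_easy``, ``restricted_nomination``);
    time-varying covariates use ``<name>_w<k>`` columns (1-based wave),
    e.g. ``smoker_w1`` or ``offlist_w2``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate actor ids in attribute table")

    @property
    def actor_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    def column(self, name: str, wave: int | None = None) -> np.ndarray:
        """Covariate values as a float array (categoricals coded)."""
        col = name if wave is None else f"{name}_w{wave + 1}"
        if col not in self.data.columns:
            if wave is not None and name in self.data.columns:
                col = name  # fixed covariate requested with a wave index
            else:
                raise KeyError(f"unknown covariate {col!r}")
        s = self.data[col]
        if s.dtype == object:
            s = pd.Series(pd.factorize(s, use_na_sentinel=True)[0],
                          index=s.index).replace(-1, np.nan)
        return s.to_numpy(dtype=float)

    def has(self, name: str) -> bool:
        return name in self.data.columns or f"{name}_w1" in self.data.columns


@dataclass
class BehaviorPanel:
    """Per-wave ordinal scores on a 1..6 scale, NaN for missing."""

    variable_name: str
    scores: np.ndarray  # (n_waves, n) float
    lo: int = 1
    hi: int = 6

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        obs = self.scores[~np.isnan(self.scores)]
        if obs.size and (np.any(obs != np.round(obs)) or obs.min() < self.lo
                         or obs.max() > self.hi):
            raise ValueError(
                f"{self.variable_name}: scores must be integers in "
                f"[{self.lo}, {self.hi}] or missing"
            )

    @property
    def n_waves(self) -> int:
        return self.scores.shape[0]

    def observed(self, wave: int) -> np.ndarray:
        return ~np.isnan(self.scores[wave])


@dataclass
class CompositionSchedule:
    """Actor presence intervals on the continuous model-time axis.

    Time runs over [0, W-1] with wave m observed at time m.  An actor is
    active on [join, leave]; outside that interval they hold no ties and
    make no changes.
    """

    joins: np.ndarray
    leaves: np.ndarray

    def __post_init__(self) -> None:
        self.joins = np.asarray(self.joins, dtype=float)
        self.leaves = np.asarray(self.leaves, dtype=float)
        if (self.joins >= self.leaves).any():
            raise ValueError("join_time must precede leave_time")

    @classmethod
    def always_present(cls, n: int, n_waves: int) -> "CompositionSchedule":
        # a single-wave panel still gets a nonempty presence interval
        return cls(np.zeros(n), np.full(n, max(float(n_waves - 1), 1.0)))

    def active_at(self, t: float) -> np.ndarray:
        return (self.joins <= t) & (t <= self.leaves)


# ---------------------------------------------------------------------------
# transforms

def top_code(scores, cap: int = 6):
    """Collapse ordinal values above ``cap`` into ``cap``.

    Raw alcohol-use intensity is reported on a 1–7 scale; sparse upper
    categories are top-coded at the sixth.  Missing values pass through.
    """
    arr = np.asarray(scores, dtype=float)
    obs = ~np.isnan(arr)
    if np.any(arr[obs] != np.round(arr[obs])):
        raise ValueError("scores must be integer-valued")
    out = arr.copy()
    out[obs & (arr > cap)] = cap
    return out


def center(values, groups=None):
    """Center a series at its grand mean, or per group if ``groups`` given.

    Missing values are ignored in the mean and preserved in the output.
    """
    arr = np.asarray(values, dtype=float)
    obs = ~np.isnan(arr)
    if not obs.any():
        raise ValueError("cannot center an all-missing series")
    out = arr.copy()
    if groups is None:
        out[obs] -= arr[obs].mean()
        return out
    groups = np.asarray(groups)
    for g in np.unique(groups):
        m = (groups == g) & obs
        if m.any():
            out[m] -= arr[m].mean()
    return out


# ---------------------------------------------------------------------------
# I/O — CSV dialect
#
# Edge lists: one file per wave, header ``wave,from,to``.  A respondent
# with no nominations appears as a row with an empty ``to`` field; an
# actor with no row at all at a wave is a non-respondent and their
# outgoing cells are missing at that wave.  Attribute table: indexed by
# ``actor_id``.  Behavior: wide by wave, columns ``<var>_w<k>``.

def _read_edge_file(path: Path, id_index: dict[str, int], wave_idx: int,
                    adjacency: np.ndarray) -> None:
    respondents: set[int] = set()
    edges: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"wave", "from", "to"} <= set(
                reader.fieldnames):
            raise ValueError(f"{path}: expected header wave,from,to")
        for row_no, row in enumerate(reader, start=2):
            src = row["from"].strip()
            if src not in id_index:
                raise ValueError(f"{path}:{row_no}: unknown actor id {src!r}")
            i = id_index[src]
            respondents.add(i)
            dst = row["to"].strip()
            if not dst:
                continue  # explicit respondent record, no nomination
            if dst not in id_index:
                raise ValueError(f"{path}:{row_no}: unknown actor id {dst!r}")
            j = id_index[dst]
            if i == j:
                raise ValueError(
                    f"{path}:{row_no}: self-tie for actor {src!r}")
            if (i, j) in seen:
                warnings.warn(f"{path}:{row_no}: duplicate edge "
                              f"{src!r}->{dst!r} dropped", stacklevel=2)
                continue
            seen.add((i, j))
            edges.append((i, j))
    n = adjacency.shape[1]
    adjacency[wave_idx] = MISSING
    for i in respondents:
        adjacency[wave_idx, i, :] = ABSENT
    for i, j in edges:
        adjacency[wave_idx, i, j] = PRESENT
    adjacency[wave_idx, np.arange(n), np.arange(n)] = ABSENT


def read_panel(
    edge_list_paths: Sequence[str | Path],
    attribute_path: str | Path,
    behavior_columns: Iterable[str] = ("alcohol",),
    behavior_path: str | Path | None = None,
    schedule_path: str | Path | None = None,
):
    """Read a multi-wave panel from the package CSV dialect.

    Returns ``(NetworkPanel, ActorTable, behaviors, schedule)`` where
    ``behaviors`` is a dict of :class:`BehaviorPanel` keyed by variable
    name and ``schedule`` is a :class:`CompositionSchedule` (everyone
    present over the full window when no sidecar is given).
    """
    attrs = pd.read_csv(attribute_path, dtype={"actor_id": str})
    if "actor_id" not in attrs.columns:
        raise ValueError(f"{attribute_path}: missing actor_id column")
    attrs = attrs.set_index("actor_id")
    table = ActorTable(attrs)
    actor_ids = table.actor_ids
    id_index = {a: k for k, a in enumerate(actor_ids)}
    n, n_waves = len(actor_ids), len(edge_list_paths)

    adjacency = np.zeros((n_waves, n, n), dtype=np.int8)
    for w, path in enumerate(edge_list_paths):
        _read_edge_file(Path(path), id_index, w, adjacency)
    panel = NetworkPanel([f"w{w + 1}" for w in range(n_waves)],
                         adjacency, actor_ids)

    beh_source = attrs if behavior_path is None else pd.read_csv(
        behavior_path, dtype={"actor_id": str}).set_index("actor_id").loc[
            actor_ids]
    behaviors: dict[str, BehaviorPanel] = {}
    for var in behavior_columns:
        cols = [f"{var}_w{w + 1}" for w in range(n_waves)]
        for c in cols:
            if c not in beh_source.columns:
                raise ValueError(f"behavior column {c!r} not found")
        scores = beh_source[cols].to_numpy(dtype=float).T
        behaviors[var] = BehaviorPanel(var, scores)

    if schedule_path is not None:
        with open(schedule_path) as fh:
            raw = json.load(fh)
        joins = np.zeros(n)
        leaves = np.full(n, float(n_waves - 1))
        for a, (j, l) in raw.items():
            joins[id_index[a]] = j
            leaves[id_index[a]] = l
        schedule = CompositionSchedule(joins, leaves)
    else:
        schedule = CompositionSchedule.always_present(n, n_waves)
    return panel, table, behaviors, schedule


def write_panel(
    out_dir: str | Path,
    panel: NetworkPanel,
    table: ActorTable,
    behaviors: dict[str, BehaviorPanel],
    schedule: CompositionSchedule | None = None,
    prefix: str = "panel",
) -> dict[str, Path]:
    """Write a panel in exactly the dialect :func:`read_panel` accepts.

    Returns a manifest mapping logical names to written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    for w in range(panel.n_waves):
        path = out / f"{prefix}_edges_w{w + 1}.csv"
        resp = panel.respondent_mask(w)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["wave", "from", "to"])
            for i in np.flatnonzero(resp):
                js = np.flatnonzero(panel.adjacency[w, i] == PRESENT)
                if js.size == 0:
                    writer.writerow([w + 1, panel.actor_ids[i], ""])
                for j in js:
                    writer.writerow([w + 1, panel.actor_ids[i],
                                     panel.actor_ids[j]])
        manifest[f"edges_w{w + 1}"] = path

    apath = out / f"{prefix}_attributes.csv"
    table.data.rename_axis("actor_id").to_csv(apath)
    manifest["attributes"] = apath

    bpath = out / f"{prefix}_behavior.csv"
    bdf = pd.DataFrame(index=pd.Index(panel.actor_ids, name="actor_id"))
    for var, bp in behaviors.items():
        for w in range(bp.n_waves):
            col = bp.scores[w]
            bdf[f"{var}_w{w + 1}"] = [
                "" if np.isnan(v) else int(v) for v in col]
    bdf.to_csv(bpath)
    manifest["behavior"] = bpath

    if schedule is not None:
        spath = out / f"{prefix}_schedule.json"
        full = (schedule.joins == 0) & (
            schedule.leaves == panel.n_waves - 1)
        payload = {
            panel.actor_ids[i]: [float(schedule.joins[i]),
                                 float(schedule.leaves[i])]
            for i in np.flatnonzero(~full)
        }
        with open(spath, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        manifest["schedule"] = spath
    return manifest
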