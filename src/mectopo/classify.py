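"""Shuffle-based null distributions and functional cell classification.

For every cell the activity series is circularly shifted against the
tracking by random offsets; each shift yields a score sample, building a
per-cell null distribution.  A cell passes a class criterion when its
observed score exceeds the chosen percentile (95 or 99) of its own null.
Object-vector cells use combined criteria over two object sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from skimage import measure

from ._util import pearson_pairwise, spawn_seed
from .synthio import ArenaSpec, Trajectory
from . import tuning

SCORE_CLASS = {"grid_score": "grid", "mvl": "hd", "border_score": "border", "ov_score": "ov"}


@dataclass
class NullDistribution:
    cell_id: str
    score_name: str
    samples: np.ndarray
    p95: float = field(init=False)
    p99: float = field(init=False)

    def __post_init__(self):
        # "higher" makes P(exceed) = (n+1-ceil(q(n-1))-1)/(n+1) ~ 1-q exactly;
        # linear interpolation would inflate the nominal pass rate
        self.p95 = self.percentile(95)
        self.p99 = self.percentile(99)

    def percentile(self, q: float) -> float:
        finite = self.samples[np.isfinite(self.samples)]
        if not len(finite):
            return float("nan")
        return float(np.percentile(finite, q, method="higher"))


def shuffle_null(
    events: np.ndarray,
    traj: Trajectory,
    score_fn: Callable[[np.ndarray, Trajectory], float],
    n_shuffles: int = 300,
    min_shift_s: float = 30.0,
    seed: int = 0,
    cell_id: str = "",
    score_name: str = "",
) -> NullDistribution:
    """Null score distribution from circular time shifts of the event series.

    Each shuffle shifts events by a uniform offset in
    [min_shift_s, T - min_shift_s], preserving the series' autocorrelation
    while breaking its alignment to behavior.
    """
    total_s = traj.n_frames * traj.dt
    if min_shift_s >= total_s / 2:
        raise ValueError("min_shift_s must be below half the session length")
    rng = spawn_seed(seed, 4)
    shifts_s = rng.uniform(min_shift_s, total_s - min_shift_s, size=n_shuffles)
    samples = np.empty(n_shuffles)
    for i, s in enumerate(shifts_s):
        k = int(round(s * traj.fps)) % traj.n_frames
        samples[i] = score_fn(np.roll(events, k), traj)
    return NullDistribution(cell_id, score_name, samples)


@dataclass
class CellLabel:
    cell_id: str
    flags: dict[str, bool]
    purity: str                    # pure | conjunctive | none | unclassifiable
    percentile: int
    label: str = ""                # the single class when pure

    def __post_init__(self):
        n = sum(self.flags.values())
        if self.purity != "unclassifiable":
            self.purity = "pure" if n == 1 else ("conjunctive" if n >= 2 else "none")
        if self.purity == "pure":
            self.label = next(c for c, f in self.flags.items() if f)


def classify_cells(
    scores: pd.DataFrame,
    nulls: Mapping[tuple[str, str], NullDistribution],
    percentile: int = 95,
    ov_pass: Mapping[str, bool] | None = None,
) -> pd.DataFrame:
    """Assign pass flags and purity labels per cell.

    ``scores`` has one row per cell_id with columns grid_score, mvl,
    border_score (ov handled via ``ov_pass``, the outcome of the combined
    object-vector criteria).  A grid/hd/border flag is set when the observed
    score strictly exceeds the chosen percentile of that cell's null.  Cells
    with a missing null for an available score are marked unclassifiable.
    """
    if percentile not in (95, 99):
        raise ValueError("percentile must be 95 or 99")
    ov_pass = ov_pass or {}
    out = []
    for row in scores.itertuples():
        cid = str(row.cell_id)
        flags = {}
        unclassifiable = False
        for score_name, cls in SCORE_CLASS.items():
            if cls == "ov":
                flags["ov"] = bool(ov_pass.get(cid, False))
                continue
            obs = getattr(row, score_name, float("nan"))
            if not np.isfinite(obs):
                flags[cls] = False
                continue
            null = nulls.get((cid, score_name))
            if null is None:
                unclassifiable = True
                flags[cls] = False
                continue
            cut = null.p95 if percentile == 95 else null.p99
            flags[cls] = bool(np.isfinite(cut) and obs > cut)
        lab = CellLabel(cid, flags, "unclassifiable" if unclassifiable else "", percentile)
        out.append({"cell_id": cid, **{f"pass_{c}": f for c, f in lab.flags.items()},
                    "purity": lab.purity, "label": lab.label, "percentile": percentile})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# combined object-vector criteria (two object sessions)
# ---------------------------------------------------------------------------


@dataclass
class OVCriteria:
    ov_score: float
    null1_p: float
    null2_p: float
    passes_null: bool
    field_away_from_walls: bool
    moves_with_object: bool

    @property
    def passed(self) -> bool:
        return self.passes_null and self.field_away_from_walls and self.moves_with_object


def evaluate_ov_criteria(
    events1: np.ndarray,
    traj1: Trajectory,
    object1: tuple[float, float],
    events2: np.ndarray,
    traj2: Trajectory,
    object2: tuple[float, float],
    arena: ArenaSpec,
    percentile: int = 95,
    n_shuffles: int = 100,
    seed: int = 0,
    cell_id: str = "",
) -> OVCriteria:
    """Combined object-vector cell criteria over two object sessions.

    (i) the cross-session OV score exceeds the chosen percentile of shuffle
    nulls built by shifting either session's events; (ii) the best-matching
    field sits at least one field-width away from the arena walls (excluding
    border-cell confusion); (iii) the arena-frame map correlation between the
    two sessions is lower than the object-frame correlation (the field moves
    with the object).
    """
    m1 = tuning.object_vector_map(events1, traj1, object1, arena)
    m2 = tuning.object_vector_map(events2, traj2, object2, arena)
    obs = tuning.ov_score(m1, m2)

    def score_shift1(ev, _traj):
        return tuning.ov_score(tuning.object_vector_map(ev, traj1, object1, arena), m2)

    def score_shift2(ev, _traj):
        return tuning.ov_score(m1, tuning.object_vector_map(ev, traj2, object2, arena))

    n1 = shuffle_null(events1, traj1, score_shift1, n_shuffles, seed=seed, cell_id=cell_id)
    n2 = shuffle_null(events2, traj2, score_shift2, n_shuffles, seed=seed + 1, cell_id=cell_id)
    q = 95 if percentile == 95 else 99
    c1, c2 = n1.percentile(q), n2.percentile(q)
    passes_null = bool(np.isfinite(obs) and obs > c1 and obs > c2)

    rm1 = tuning.compute_ratemap(events1, traj1, arena)
    rm2 = tuning.compute_ratemap(events2, traj2, arena)
    away = _field_away_from_walls(rm1, arena)

    arena_r = pearson_pairwise(rm1.rate, rm2.rate, min_n=20)
    moves = bool(np.isfinite(obs) and (not np.isfinite(arena_r) or arena_r < obs))
    return OVCriteria(obs, c1, c2, passes_null, away, moves)


def _field_away_from_walls(rm: tuning.RateMap, arena: ArenaSpec) -> bool:
    rate = np.nan_to_num(rm.rate)
    peak = rate.max()
    if peak <= 0:
        return False
    labels = measure.label(rate >= 0.3 * peak)
    py, px = np.unravel_index(np.argmax(rate), rate.shape)
    fid = labels[py, px]
    ys, xs = np.nonzero(labels == fid)
    # field must not reach the wall: centroid at least one equivalent radius away
    radius = np.sqrt(len(ys) / np.pi)
    cy, cx = ys.mean(), xs.mean()
    ny, nx = rate.shape
    wall_dist = min(cx, nx - 1 - cx, cy, ny - 1 - cy)
    return bool(wall_dist >= radius)


# ---------------------------------------------------------------------------
# score-function factories for shuffling
# ---------------------------------------------------------------------------


def make_score_fn(score_name: str, arena: ArenaSpec | None = None,
                  speed_min_cms: float = tuning.DEFAULT_SPEED_MIN_CMS):
    """Closure computing one named score from (events, traj), for shuffle_null."""
    arena = arena or ArenaSpec()

    def fn(events: np.ndarray, traj: Trajectory) -> float:
        if score_name == "mvl":
            try:
                return tuning.mvl(tuning.hd_tuning(events, traj, speed_min_cms=speed_min_cms))
            except ValueError:
                return float("nan")
        rm = tuning.compute_ratemap(events, traj, arena, speed_min_cms=speed_min_cms)
        if score_name == "grid_score":
            try:
                return tuning.grid_score(tuning.grid_autocorrelogram(rm))
            except ValueError:
                return float("nan")
        if score_name == "border_score":
            return tuning.border_score(rm)
        if score_name == "spatial_info":
            occ = tuning.compute_occupancy(traj, arena, speed_min_cms)
            return tuning.spatial_information(rm, occ)
        raise ValueError(f"unknown score {score_name!r}")

    return fn
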