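"""Synthetic open-field imaging sessions with known ground truth.

Emulates miniscope recordings of spatially modulated neurons in medial
entorhinal cortex (MEC): a foraging trajectory in a square arena sampled at
~7.52 fps, an ensemble of cells with parametric tuning (hexagonal grid
fields, von Mises head-direction tuning, wall-hugging border fields,
object-anchored vector fields, untuned cells), anatomical soma positions in
a ~367x558 um field of view, and per-frame deconvolved event amplitudes.

Every random quantity flows from a single integer seed, so a session is
bitwise reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import spawn_seed, wrap_deg

CELL_CLASSES = ("grid", "hd", "border", "ov", "untuned")

#: amplitude dispersion of single deconvolved events (lognormal sigma)
EVENT_AMP_SIGMA = 0.5
#: calcium indicator decay used for optional dF/F traces (GCaMP6-like), seconds
CALCIUM_TAU_S = 1.5


class IntegrityError(ValueError):
    """A session's pieces are mutually inconsistent."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArenaSpec:
    """Square open-field arena with optional discrete objects."""

    side_cm: float = 80.0
    bin_cm: float = 2.5
    objects: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        if self.side_cm <= 0 or self.bin_cm <= 0:
            raise ValueError("side_cm and bin_cm must be positive")
        n = self.side_cm / self.bin_cm
        if abs(n - round(n)) > 1e-9 or round(n) < 8:
            raise ValueError("side_cm/bin_cm must be an integer >= 8")
        for (ox, oy) in self.objects:
            if not (0 < ox < self.side_cm and 0 < oy < self.side_cm):
                raise ValueError("objects must lie strictly inside the arena")

    @property
    def n_bins(self) -> int:
        return int(round(self.side_cm / self.bin_cm))


@dataclass
class Trajectory:
    """Time-stamped position and head direction of a foraging animal."""

    t_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    hd_deg: np.ndarray
    fps: float = 7.52

    def __post_init__(self):
        n = len(self.t_s)
        if not (len(self.x_cm) == len(self.y_cm) == len(self.hd_deg) == n):
            raise ValueError("trajectory arrays must share one length")

    @property
    def n_frames(self) -> int:
        return len(self.t_s)

    @property
    def dt(self) -> float:
        return 1.0 / self.fps

    def speed_cms(self) -> np.ndarray:
        """Per-frame running speed (forward difference, last value repeated)."""
        dx = np.diff(self.x_cm)
        dy = np.diff(self.y_cm)
        dt = np.diff(self.t_s)
        v = np.hypot(dx, dy) / dt
        return np.append(v, v[-1] if len(v) else 0.0)


@dataclass
class GroundTruthCell:
    """One simulated neuron: anatomical position, class, tuning parameters."""

    cell_id: str
    true_class: str
    params: dict
    peak_rate: float
    anat_x_um: float
    anat_y_um: float
    region: str = "MEC"

    def __post_init__(self):
        if self.true_class not in CELL_CLASSES:
            raise ValueError(f"unknown class {self.true_class!r}")
        if self.peak_rate <= 0:
            raise ValueError("peak_rate must be positive")


@dataclass
class EnsembleSpec:
    """Layout and composition of a simulated field of view."""

    counts: Mapping[str, int]
    fov_um: tuple[float, float] = (367.0, 558.0)
    layout: str = "intermingled"
    cluster_sigma_um: float | None = None
    boundary_x_um: float | None = None
    #: territory layouts: fraction of cells placed uniformly regardless of side
    mixing: float = 0.0
    #: territory layouts: which side of the boundary each class occupies
    territory_sides: Mapping[str, str] | None = None
    #: clustered layouts: fixed per-class cluster centers (µm); random if absent
    cluster_centers: Mapping[str, tuple[float, float]] | None = None
    seed: int = 0

    def __post_init__(self):
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be non-negative")
        if self.layout not in ("intermingled", "clustered", "territory"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.layout == "clustered" and not (self.cluster_sigma_um or 0) > 0:
            raise ValueError("clustered layout requires cluster_sigma_um > 0")
        if self.layout == "territory" and self.boundary_x_um is None:
            raise ValueError("territory layout requires boundary_x_um")
        if not 0 <= self.mixing < 1:
            raise ValueError("mixing must be in [0, 1)")


@dataclass
class ActivitySeries:
    """Per-frame deconvolved event amplitudes, optionally a dF/F trace."""

    events: np.ndarray
    dff: np.ndarray | None = None
    snr: float = 0.0

    def __post_init__(self):
        if np.any(~np.isfinite(self.events)) or np.any(self.events < 0):
            raise ValueError("events must be finite and non-negative")


@dataclass
class Session:
    """One recording: arena, trajectory, cells, and their activity."""

    arena: ArenaSpec
    trajectory: Trajectory
    cells: list[GroundTruthCell]
    activities: dict[str, ActivitySeries]
    protocol: str = "baseline"
    seed: int = 0


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------


def simulate_trajectory(
    duration_s: float,
    arena: ArenaSpec | None = None,
    fps: float = 7.52,
    speed_mean_cms: float = 15.0,
    seed: int = 0,
    hd_noise_deg: float = 8.0,
) -> Trajectory:
    """Simulate a foraging path: Ornstein-Uhlenbeck speed, random-walk heading.

    The heading diffuses (turn-rate noise) and the speed relaxes toward
    ``speed_mean_cms``.  Near walls the heading is steered smoothly toward
    the arena center (reducing unrealistic wall-running); residual wall
    contacts reflect both position and heading.  Head direction is the
    movement heading plus small wrapped Gaussian noise, emulating imperfect
    head-body alignment.
    """
    if duration_s <= 0 or fps <= 0:
        raise ValueError("duration_s and fps must be positive")
    if speed_mean_cms < 0:
        raise ValueError("speed_mean_cms must be non-negative")
    arena = arena or ArenaSpec()
    rng = spawn_seed(seed, 0)
    n = int(np.floor(duration_s * fps))
    dt = 1.0 / fps
    side = arena.side_cm

    # parameters chosen for realistic open-field coverage at 20-min sessions
    theta_speed = 0.8          # 1/s relaxation of speed toward the mean
    sigma_speed = 0.5 * speed_mean_cms   # scales with mean: zero mean => frozen
    sigma_turn = 1.4           # rad/sqrt(s) heading diffusion

    x = np.empty(n)
    y = np.empty(n)
    heading = np.empty(n)
    x[0] = rng.uniform(0.25 * side, 0.75 * side)
    y[0] = rng.uniform(0.25 * side, 0.75 * side)
    heading[0] = rng.uniform(0, 2 * np.pi)
    v = speed_mean_cms

    wall_margin = 0.10 * side   # smooth steering toward the center near walls
    steer_gain = 1.5            # 1/s

    turn_noise = rng.normal(0.0, sigma_turn * np.sqrt(dt), size=n)
    speed_noise = rng.normal(0.0, sigma_speed * np.sqrt(dt), size=n)
    for i in range(1, n):
        v = v + theta_speed * (speed_mean_cms - v) * dt + speed_noise[i]
        v = max(v, 0.0)
        h = heading[i - 1] + turn_noise[i]
        d_wall = min(x[i - 1], side - x[i - 1], y[i - 1], side - y[i - 1])
        if d_wall < wall_margin:
            to_center = np.arctan2(side / 2 - y[i - 1], side / 2 - x[i - 1])
            diff = np.angle(np.exp(1j * (to_center - h)))
            h += steer_gain * (1.0 - d_wall / wall_margin) * diff * dt
        nx = x[i - 1] + v * np.cos(h) * dt
        ny = y[i - 1] + v * np.sin(h) * dt
        # reflect off walls, flipping the corresponding heading component
        if nx < 0:
            nx = -nx
            h = np.pi - h
        elif nx > side:
            nx = 2 * side - nx
            h = np.pi - h
        if ny < 0:
            ny = -ny
            h = -h
        elif ny > side:
            ny = 2 * side - ny
            h = -h
        x[i], y[i], heading[i] = nx, ny, h

    hd = np.degrees(heading) + rng.normal(0.0, hd_noise_deg, size=n)
    t = np.arange(n) * dt
    return Trajectory(t_s=t, x_cm=x, y_cm=y, hd_deg=np.asarray(wrap_deg(hd)), fps=fps)


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

#: documented priors for tuning parameters, per class
def _draw_params(cls: str, rng: np.random.Generator, arena: ArenaSpec) -> dict:
    if cls == "grid":
        return {
            "spacing_cm": float(rng.uniform(35.0, 55.0)),
            "orientation_deg": float(rng.uniform(0.0, 60.0)),
            "phase_x_cm": float(rng.uniform(0.0, 55.0)),
            "phase_y_cm": float(rng.uniform(0.0, 55.0)),
        }
    if cls == "hd":
        return {
            "preferred_deg": float(rng.uniform(0.0, 360.0)),
            "concentration": float(rng.uniform(4.0, 8.0)),
        }
    if cls == "border":
        return {
            "wall": int(rng.integers(0, 4)),  # 0:W 1:E 2:S 3:N
            "depth_cm": float(rng.uniform(4.0, 8.0)),
        }
    if cls == "ov":
        return {
            "r_cm": float(rng.uniform(10.0, 30.0)),
            "theta_deg": float(rng.uniform(0.0, 360.0)),
            "width_cm": float(rng.uniform(6.0, 10.0)),
        }
    return {}


def make_ensemble(spec: EnsembleSpec, arena: ArenaSpec | None = None) -> list[GroundTruthCell]:
    """Draw an ensemble of ground-truth cells with the requested layout.

    ``intermingled``: soma positions uniform over the FOV.
    ``clustered``: one Gaussian cluster center per class (sd ``cluster_sigma_um``).
    ``territory``: classes segregate across ``boundary_x_um`` (grid cells on the
    low-x side by default, all others high-x); a ``mixing`` fraction of cells is
    placed uniformly, softening the boundary.  Territory cells are labeled
    MEC/PAS by the side they land on; other layouts are all MEC.
    """
    arena = arena or ArenaSpec()
    rng = spawn_seed(spec.seed, 1)
    w, h = spec.fov_um
    cells: list[GroundTruthCell] = []

    sides = dict(spec.territory_sides or {})
    centers: dict[str, tuple[float, float]] = {}
    if spec.layout == "clustered":
        fixed = dict(spec.cluster_centers or {})
        for cls in spec.counts:
            centers[cls] = fixed.get(
                cls, (rng.uniform(0.15 * w, 0.85 * w), rng.uniform(0.15 * h, 0.85 * h))
            )

    idx = 0
    for cls in CELL_CLASSES:
        n_cls = int(spec.counts.get(cls, 0))
        # territory: a fixed number of each class ignores the boundary
        n_mixed = int(round(spec.mixing * n_cls))
        for j in range(n_cls):
            if spec.layout == "intermingled":
                px, py = rng.uniform(0, w), rng.uniform(0, h)
            elif spec.layout == "clustered":
                cx, cy = centers[cls]
                while True:
                    px = rng.normal(cx, spec.cluster_sigma_um)
                    py = rng.normal(cy, spec.cluster_sigma_um)
                    if 0 <= px <= w and 0 <= py <= h:
                        break
            else:  # territory
                b = float(spec.boundary_x_um)
                side = sides.get(cls, "low" if cls == "grid" else "high")
                if j < n_mixed:
                    px = rng.uniform(0, w)
                elif side == "low":
                    px = rng.uniform(0, min(b, w))
                else:
                    px = rng.uniform(min(b, w), w)
                py = rng.uniform(0, h)
            region = "MEC"
            if spec.layout == "territory":
                region = "MEC" if px < float(spec.boundary_x_um) else "PAS"
            peak = float(np.exp(rng.normal(np.log(1.5 if cls != "untuned" else 0.5), 0.3)))
            cells.append(
                GroundTruthCell(
                    cell_id=f"c{idx:04d}",
                    true_class=cls,
                    params=_draw_params(cls, rng, arena),
                    peak_rate=peak,
                    anat_x_um=float(px),
                    anat_y_um=float(py),
                    region=region,
                )
            )
            idx += 1
    return cells


# ---------------------------------------------------------------------------
# activity
# ---------------------------------------------------------------------------


def _grid_rate(x, y, p):
    """Thresholded sum of three cosines on a hexagonal lattice, in [0, 1]."""
    k = 4 * np.pi / (np.sqrt(3) * p["spacing_cm"])
    base = np.deg2rad(p["orientation_deg"])
    dx = x - p["phase_x_cm"]
    dy = y - p["phase_y_cm"]
    s = np.zeros_like(dx)
    for j in range(3):
        a = base + j * np.pi / 3
        s += np.cos(k * (dx * np.cos(a) + dy * np.sin(a)))
    return np.maximum(0.0, s / 3.0)


def rate_model(cell: GroundTruthCell, traj: Trajectory, arena: ArenaSpec) -> np.ndarray:
    """Per-frame expected event rate (events/s) for a ground-truth cell."""
    p = cell.params
    cls = cell.true_class
    if cls == "grid":
        shape = _grid_rate(traj.x_cm, traj.y_cm, p)
    elif cls == "hd":
        kappa = p["concentration"]
        d = np.deg2rad(traj.hd_deg - p["preferred_deg"])
        if np.isinf(kappa):
            shape = (np.abs(np.mod(np.degrees(d) + 180, 360) - 180) < 3.0).astype(float)
        else:
            shape = np.exp(kappa * (np.cos(d) - 1.0))
    elif cls == "border":
        wall = p["wall"]
        dist = [traj.x_cm, arena.side_cm - traj.x_cm, traj.y_cm, arena.side_cm - traj.y_cm][wall]
        shape = np.exp(-np.maximum(dist, 0.0) / p["depth_cm"])
    elif cls == "ov":
        if not arena.objects:
            raise IntegrityError("object-vector cell in an arena without objects")
        shape = np.zeros(traj.n_frames)
        th = np.deg2rad(p["theta_deg"])
        for (ox, oy) in arena.objects:
            cx = ox + p["r_cm"] * np.cos(th)
            cy = oy + p["r_cm"] * np.sin(th)
            d2 = (traj.x_cm - cx) ** 2 + (traj.y_cm - cy) ** 2
            shape = np.maximum(shape, np.exp(-d2 / (2 * p["width_cm"] ** 2)))
    else:  # untuned
        shape = np.ones(traj.n_frames)
    return cell.peak_rate * shape


def generate_activity(
    cell: GroundTruthCell,
    traj: Trajectory,
    arena: ArenaSpec | None = None,
    noise_level: float = 0.0,
    seed: int = 0,
    make_dff: bool = False,
) -> ActivitySeries:
    """Draw per-frame event amplitudes from the cell's rate model.

    Events are Poisson counts per frame scaled by heavy-tailed (lognormal)
    single-event amplitudes, mimicking deconvolved calcium transients.  When
    ``make_dff`` is set (or ``noise_level`` > 0) a dF/F trace is produced by
    convolving events with a single-exponential indicator kernel plus
    Gaussian noise of sd ``noise_level``.
    """
    arena = arena or ArenaSpec()
    rng = spawn_seed(seed, 2, zlib.crc32(cell.cell_id.encode()) & 0x7FFFFFFF)
    lam = rate_model(cell, traj, arena)
    counts = rng.poisson(lam * traj.dt)
    events = np.zeros(traj.n_frames)
    nz = np.nonzero(counts)[0]
    if len(nz):
        total = int(counts[nz].sum())
        amps = np.exp(rng.normal(0.0, EVENT_AMP_SIGMA, size=total))
        frame_of = np.repeat(nz, counts[nz])
        events = np.bincount(frame_of, weights=amps, minlength=traj.n_frames)

    dff = None
    if make_dff or noise_level > 0:
        kernel = np.exp(-np.arange(0, 8 * CALCIUM_TAU_S, traj.dt) / CALCIUM_TAU_S)
        dff = np.convolve(events, kernel)[: traj.n_frames]
        dff = dff + rng.normal(0.0, noise_level, size=traj.n_frames)
    return ActivitySeries(events=events, dff=dff)


# ---------------------------------------------------------------------------
# session assembly and (de)serialization
# ---------------------------------------------------------------------------

_PROTOCOL_OBJECTS = {"baseline": 0, "object1": 1, "object2": 1}


def assemble_session(
    arena: ArenaSpec,
    traj: Trajectory,
    cells: Sequence[GroundTruthCell],
    activities: Mapping[str, ActivitySeries],
    protocol: str = "baseline",
    seed: int = 0,
) -> Session:
    """Bundle the pieces into a Session, checking mutual consistency."""
    if protocol not in _PROTOCOL_OBJECTS:
        raise ValueError(f"unknown protocol {protocol!r}")
    need = _PROTOCOL_OBJECTS[protocol]
    if need == 0 and arena.objects:
        raise IntegrityError("baseline protocol must have no objects")
    if need > 0 and len(arena.objects) < 1:
        raise IntegrityError(f"protocol {protocol!r} requires at least one object")
    for c in cells:
        if c.cell_id not in activities:
            raise IntegrityError(f"missing activity for cell {c.cell_id}")
        if len(activities[c.cell_id].events) != traj.n_frames:
            raise IntegrityError(f"activity length mismatch for {c.cell_id}")
    return Session(arena, traj, list(cells), dict(activities), protocol, seed)


def simulate_session(
    spec: EnsembleSpec,
    arena: ArenaSpec | None = None,
    duration_s: float = 1200.0,
    fps: float = 7.52,
    speed_mean_cms: float = 15.0,
    noise_level: float = 0.0,
    protocol: str = "baseline",
    seed: int | None = None,
) -> Session:
    """End-to-end session simulation from an ensemble spec (one seed)."""
    seed = spec.seed if seed is None else seed
    arena = arena or ArenaSpec()
    traj = simulate_trajectory(duration_s, arena, fps, speed_mean_cms, seed=seed)
    cells = make_ensemble(replace(spec, seed=seed), arena)
    acts = {
        c.cell_id: generate_activity(c, traj, arena, noise_level, seed=seed)
        for c in cells
    }
    return assemble_session(arena, traj, cells, acts, protocol, seed)


def write_session(session: Session, out_dir: str | Path) -> Path:
    """Serialize a session to one directory of plain-text files.

    Layout: ``tracking.csv`` (frame,t_s,x_cm,y_cm,hd_deg), ``events.csv``
    (long: cell_id,frame,amplitude), ``cells.csv`` (cell_id,anat_x_um,
    anat_y_um,region,true_class), ``session.json`` (arena, protocol, fps,
    seed, tuning parameters), optional ``dff.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tr = session.trajectory
    pd.DataFrame(
        {"frame": np.arange(tr.n_frames), "t_s": tr.t_s, "x_cm": tr.x_cm,
         "y_cm": tr.y_cm, "hd_deg": tr.hd_deg}
    ).to_csv(out / "tracking.csv", index=False)

    rows = []
    for cid, act in session.activities.items():
        nz = np.nonzero(act.events)[0]
        rows.append(pd.DataFrame({"cell_id": cid, "frame": nz, "amplitude": act.events[nz]}))
    ev = (pd.concat(rows, ignore_index=True) if rows else
          pd.DataFrame(columns=["cell_id", "frame", "amplitude"]))
    ev.to_csv(out / "events.csv", index=False)

    pd.DataFrame(
        [{"cell_id": c.cell_id, "anat_x_um": c.anat_x_um, "anat_y_um": c.anat_y_um,
          "region": c.region, "true_class": c.true_class} for c in session.cells]
    ).to_csv(out / "cells.csv", index=False)

    dffs = {cid: a.dff for cid, a in session.activities.items() if a.dff is not None}
    if dffs:
        pd.DataFrame(dffs).to_csv(out / "dff.csv", index=False)

    meta = {
        "arena": {"side_cm": session.arena.side_cm, "bin_cm": session.arena.bin_cm,
                  "objects": [list(o) for o in session.arena.objects]},
        "protocol": session.protocol,
        "fps": session.trajectory.fps,
        "seed": session.seed,
        "cells": {c.cell_id: {"params": c.params, "peak_rate": c.peak_rate,
                              "snr": session.activities[c.cell_id].snr}
                  for c in session.cells},
    }
    (out / "session.json").write_text(json.dumps(meta, indent=1))
    return out


def read_session(in_dir: str | Path) -> Session:
    """Load a session directory written by :func:`write_session`."""
    src = Path(in_dir)
    meta = json.loads((src / "session.json").read_text())
    arena = ArenaSpec(
        side_cm=meta["arena"]["side_cm"],
        bin_cm=meta["arena"]["bin_cm"],
        objects=tuple(tuple(o) for o in meta["arena"]["objects"]),
    )
    tr = pd.read_csv(src / "tracking.csv")
    traj = Trajectory(
        t_s=tr["t_s"].to_numpy(), x_cm=tr["x_cm"].to_numpy(),
        y_cm=tr["y_cm"].to_numpy(), hd_deg=tr["hd_deg"].to_numpy(),
        fps=float(meta["fps"]),
    )
    cdf = pd.read_csv(src / "cells.csv")
    cells = [
        GroundTruthCell(
            cell_id=str(r.cell_id), true_class=str(r.true_class),
            params=meta["cells"][str(r.cell_id)]["params"],
            peak_rate=meta["cells"][str(r.cell_id)]["peak_rate"],
            anat_x_um=float(r.anat_x_um), anat_y_um=float(r.anat_y_um),
            region=str(r.region),
        )
        for r in cdf.itertuples()
    ]
    ev = pd.read_csv(src / "events.csv")
    dff_df = pd.read_csv(src / "dff.csv") if (src / "dff.csv").exists() else None
    activities = {}
    n = traj.n_frames
    for c in cells:
        events = np.zeros(n)
        sub = ev[ev["cell_id"] == c.cell_id]
        events[sub["frame"].to_numpy(dtype=int)] = sub["amplitude"].to_numpy()
        dff = None
        if dff_df is not None and c.cell_id in dff_df.columns:
            dff = dff_df[c.cell_id].to_numpy()
        activities[c.cell_id] = ActivitySeries(
            events=events, dff=dff, snr=float(meta["cells"][c.cell_id].get("snr", 0.0))
        )
    return assemble_session(arena, traj, cells, activities, meta["protocol"], meta.get("seed", 0))


# ---------------------------------------------------------------------------
# reference anatomical scenarios
# ---------------------------------------------------------------------------

#: territory scenario: a 300-cell FOV straddling the MEC/PAS boundary, with
#: grid cells dorso-medial of it; the mixing fraction is calibrated so the
#: grid-vs-other normalized NN distance averages ~1.13 across sessions
TERRITORY_COUNTS = {"grid": 100, "hd": 100, "border": 50, "ov": 50}
TERRITORY_BOUNDARY_UM = 180.0
TERRITORY_MIXING = 0.58

#: clustered scenario: one grid-cell cluster over an intermingled background
#: (300 cells total); sigma calibrated so the within-class normalized 5-NN
#: distance of grid starters averages ~0.94
CLUSTERED_GRID_COUNT = 100
CLUSTERED_OTHER_COUNTS = {"hd": 70, "border": 70, "untuned": 60}
CLUSTERED_SIGMA_UM = 180.0


def _cells_frame(cells: Sequence[GroundTruthCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"cell_id": c.cell_id, "anat_x_um": c.anat_x_um, "anat_y_um": c.anat_y_um,
          "label": c.true_class, "region": c.region} for c in cells]
    )


def territory_fov(seed: int) -> pd.DataFrame:
    """One territory-layout FOV (positions, class labels, regions) at the
    calibrated anatomical effect size."""
    spec = EnsembleSpec(counts=TERRITORY_COUNTS, layout="territory",
                        boundary_x_um=TERRITORY_BOUNDARY_UM,
                        mixing=TERRITORY_MIXING, seed=seed)
    return _cells_frame(make_ensemble(spec))


def clustered_grid_fov(seed: int) -> pd.DataFrame:
    """One FOV with a grid-cell cluster over an intermingled background at the
    calibrated clustering effect size."""
    g = make_ensemble(EnsembleSpec(counts={"grid": CLUSTERED_GRID_COUNT},
                                   layout="clustered",
                                   cluster_sigma_um=CLUSTERED_SIGMA_UM, seed=seed))
    rest = make_ensemble(EnsembleSpec(counts=CLUSTERED_OTHER_COUNTS,
                                      layout="intermingled", seed=seed + 500_000))
    return _cells_frame(g + rest)


# ---------------------------------------------------------------------------
# class-conditional score priors (for layout-level analyses)
# ---------------------------------------------------------------------------

#: (mean, sd) of each score for cells of each class; off-class scores hover
#: near the untuned baseline.  Used where an analysis operates on scores and
#: anatomical layout only, without simulating activity frame by frame.
_SCORE_PRIORS = {
    "grid_score": {"grid": (0.9, 0.25), "_": (0.0, 0.18)},
    "border_score": {"border": (0.65, 0.12), "_": (0.0, 0.15)},
    "mvl": {"hd": (0.65, 0.12), "_": (0.12, 0.06)},
    "ov_score": {"ov": (0.6, 0.15), "_": (0.0, 0.12)},
    "spatial_info": {"grid": (1.2, 0.4), "border": (0.9, 0.3), "ov": (1.0, 0.35),
                     "hd": (0.35, 0.15), "_": (0.25, 0.12)},
}


def sample_scores(cells: Sequence[GroundTruthCell], seed: int = 0) -> pd.DataFrame:
    """Draw plausible tuning scores for each cell from its class-conditional prior.

    A cheap stand-in for frame-by-frame simulation plus scoring, used by
    analyses that consume (position, score) pairs only — topographic maps and
    composition sweeps.  The mvl prior is clipped to [0, 1].
    """
    rng = spawn_seed(seed, 3)
    rows = []
    for c in cells:
        row = {"cell_id": c.cell_id, "true_class": c.true_class,
               "anat_x_um": c.anat_x_um, "anat_y_um": c.anat_y_um, "region": c.region}
        for score, priors in _SCORE_PRIORS.items():
            mu, sd = priors.get(c.true_class, priors["_"])
            v = rng.normal(mu, sd)
            if score == "mvl":
                v = float(np.clip(v, 0.0, 1.0))
            row[score] = v
        rows.append(row)
    return pd.DataFrame(rows)
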