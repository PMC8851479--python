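"""Session-level cell-type composition and the grid/OV label-shuffle test.

The discrimination index (n_grid - n_ov)/(n_grid + n_ov) summarizes the
grid-versus-object-vector bias of a recording, from -1 (only OV cells) to
+1 (only grid cells).  The label-shuffle test asks how large that bias would
look by chance: a fixed fraction of a large cell pool is labeled half grid,
half OV; repeated samples the size of a typical session are drawn without
replacement and classified Grid or OV by majority; ties are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import spawn_seed

CLASSES = ("grid", "hd", "border", "ov")


@dataclass
class SessionComposition:
    counts: dict[str, int]         # pure counts per class
    fractions: dict[str, float]
    counts_incl: dict[str, int]    # including conjunctive cells
    fractions_incl: dict[str, float]
    n_cells: int
    disc_index: float              # NaN when n_grid + n_ov == 0


def disc_index(n_grid: int, n_ov: int) -> float:
    """(n_grid - n_ov)/(n_grid + n_ov); NaN when both counts are zero."""
    tot = n_grid + n_ov
    if tot == 0:
        return float("nan")
    return float((n_grid - n_ov) / tot)


def session_composition(labels: pd.DataFrame) -> SessionComposition:
    """Per-class counts/fractions from a classification table.

    ``labels`` is the classify output: columns pass_<class>, purity.  Pure
    counts require exactly one flag; the parallel tally includes conjunctive
    cells in every class they pass.
    """
    n = len(labels)
    counts, counts_incl = {}, {}
    if n == 0:
        zero = {c: 0 for c in CLASSES}
        empty = {c: float("nan") for c in CLASSES}
        return SessionComposition(zero, empty, dict(zero), dict(empty), 0, float("nan"))
    for cls in CLASSES:
        col = labels.get(f"pass_{cls}")
        passed = col.to_numpy(dtype=bool) if col is not None else np.zeros(n, bool)
        pure = passed & (labels["purity"] == "pure").to_numpy()
        counts[cls] = int(pure.sum())
        counts_incl[cls] = int(passed.sum())
    fr = {c: (counts[c] / n if n else float("nan")) for c in CLASSES}
    fr_i = {c: (counts_incl[c] / n if n else float("nan")) for c in CLASSES}
    return SessionComposition(counts, fr, counts_incl, fr_i, n,
                              disc_index(counts["grid"], counts["ov"]))


def crossclass_correlation(
    compositions: pd.DataFrame,
    min_cells: int = 15,
    min_sessions: int = 5,
) -> pd.DataFrame:
    """Spearman rank correlation of per-session class fractions, all pairs.

    ``compositions`` holds one row per session with columns ``n_cells`` and
    ``frac_<class>``.  Sessions with fewer than ``min_cells`` cells are
    dropped.  Returns a tidy frame (class_a, class_b, spearman_r, p_value, n).
    """
    kept = compositions[compositions["n_cells"] >= min_cells]
    if len(kept) < min_sessions:
        raise ValueError(f"need at least {min_sessions} sessions after the cell filter")
    rows = []
    for i, a in enumerate(CLASSES):
        for b in CLASSES[i + 1:]:
            fa = kept[f"frac_{a}"].to_numpy()
            fb = kept[f"frac_{b}"].to_numpy()
            if np.ptp(fa) == 0 or np.ptp(fb) == 0:
                r, p = float("nan"), float("nan")
            else:
                r, p = stats.spearmanr(fa, fb)
            rows.append({"class_a": a, "class_b": b, "spearman_r": float(r),
                         "p_value": float(p), "n": len(kept)})
    return pd.DataFrame(rows)


@dataclass
class GridOVShuffleResult:
    n_total: int
    n_labeled: int
    split: float
    sample_n: int
    n_grid: np.ndarray             # per-sample grid count
    n_ov: np.ndarray
    classification: np.ndarray     # "Grid" | "OV" | "tie"
    summary: dict                  # per classification: means/sds of fractions and disc

    @property
    def n_kept(self) -> int:
        return int(np.sum(self.classification != "tie"))


def gridov_shuffle_test(
    n_total: int = 4399,
    n_labeled: int = 932,
    split: float = 0.5,
    sample_n: int = 129,
    n_samples: int = 5000,
    seed: int = 0,
    relabel_per_sample: bool = False,
) -> GridOVShuffleResult:
    """Label-shuffle null for the grid/OV discrimination index.

    A fixed labeling assigns floor(n_labeled*split) cells grid and the rest
    OV within a pool of ``n_total``; each sample draws ``sample_n`` cells
    without replacement, counts grid and OV labels, and is classified by
    majority (ties excluded).  With ``relabel_per_sample`` the grid/OV split
    of the labeled cells is redrawn binomially for every sample instead.

    Sampling uses the exact distributional equivalence of index sampling:
    the labeled count in a sample is hypergeometric, and the grid count given
    that is hypergeometric (fixed labeling) or binomial (per-sample
    relabeling).
    """
    if not 0 < split < 1:
        raise ValueError("split must be in (0, 1)")
    if n_labeled > n_total or sample_n > n_total:
        raise ValueError("labeled pool and sample size must fit in the total")
    rng = spawn_seed(seed, 5)
    n_grid_pool = int(np.floor(n_labeled * split))
    n_ov_pool = n_labeled - n_grid_pool

    n_lab = rng.hypergeometric(n_labeled, n_total - n_labeled, sample_n, size=n_samples)
    if relabel_per_sample:
        g = rng.binomial(n_lab, split)
    else:
        g = np.array([rng.hypergeometric(n_grid_pool, n_ov_pool, k) if k else 0
                      for k in n_lab])
    o = n_lab - g
    cls = np.where(g > o, "Grid", np.where(o > g, "OV", "tie"))

    with np.errstate(invalid="ignore", divide="ignore"):
        disc = np.where(g + o > 0, (g - o) / np.maximum(g + o, 1), np.nan)
    summary = {}
    for name, mask in (("Grid", cls == "Grid"), ("OV", cls == "OV")):
        if mask.any():
            summary[name] = {
                "mean_disc": float(np.nanmean(disc[mask])),
                "sd_disc": float(np.nanstd(disc[mask])),
                "mean_frac_grid": float(np.mean(g[mask] / sample_n)),
                "sd_frac_grid": float(np.std(g[mask] / sample_n)),
                "mean_frac_ov": float(np.mean(o[mask] / sample_n)),
                "sd_frac_ov": float(np.std(o[mask] / sample_n)),
                "n": int(mask.sum()),
            }
    return GridOVShuffleResult(n_total, n_labeled, split, sample_n, g, o, cls, summary)
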