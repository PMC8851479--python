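"""Nearest-neighbor statistics on soma positions: interclass separation and
within-class clustering.

All statistics are normalized against label-permutation references built
from the full recorded population of a session, so values > 1 indicate
anatomical segregation between classes and values < 1 indicate clustering
within a class.  Size matching (random downsampling of the larger group)
removes the dependence of NN distances on group size.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._util import spawn_seed

DEFAULT_MIN_PAIR_UM = 10.0


def mask_region(points: pd.DataFrame, keep_region: str = "MEC") -> pd.DataFrame:
    """Retain only cells in the requested anatomical region."""
    return points[points["region"] == keep_region].reset_index(drop=True)


def _as_xy(points) -> np.ndarray:
    if isinstance(points, pd.DataFrame):
        return points[["anat_x_um", "anat_y_um"]].to_numpy(float)
    return np.asarray(points, float).reshape(-1, 2)


def _nn_mean(a: np.ndarray, b: np.ndarray, min_pair_um: float, same_set: bool = False) -> float:
    """Mean over A cells of the distance to the nearest B cell.

    Pairs closer than ``min_pair_um`` are excluded (overlapping-ROI guard);
    with ``same_set`` self-pairs are excluded as well.  A cells with no valid
    neighbor drop out of the mean.
    """
    if len(a) == 0 or len(b) == 0:
        return float("nan")
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
    if same_set and a.shape == b.shape and np.array_equal(a, b):
        np.fill_diagonal(d, np.inf)
    d[d < min_pair_um] = np.inf
    nn = d.min(axis=1)
    nn = nn[np.isfinite(nn)]
    return float(nn.mean()) if len(nn) else float("nan")


@dataclass
class NNResult:
    class_pair: tuple[str, str]
    data_mean_um: float
    reference_mean_um: float
    normalized: float
    n_starters: int
    per_subsample_um: np.ndarray


def interclass_nn(
    points_a,
    points_b,
    min_starters: int = 5,
    min_pair_um: float = DEFAULT_MIN_PAIR_UM,
    n_subsamples: int = 100,
    seed: int = 0,
    class_pair: tuple[str, str] = ("A", "B"),
) -> NNResult:
    """Mean nearest-neighbor distance from class A somata to class B somata.

    The larger class is randomly downsampled to the smaller class's size in
    each of ``n_subsamples`` rounds; the reported mean averages over rounds.
    Normalization (against a label permutation) is left NaN here; see
    :func:`label_permutation_reference` and :func:`interclass_analysis`.
    """
    a, b = _as_xy(points_a), _as_xy(points_b)
    if len(a) < min_starters or len(b) < min_starters:
        raise ValueError(
            f"both classes need >= {min_starters} cells (got {len(a)}, {len(b)})"
        )
    rng = spawn_seed(seed, 6)
    m = min(len(a), len(b))
    means = np.empty(n_subsamples)
    for i in range(n_subsamples):
        aa = a if len(a) == m else a[rng.choice(len(a), m, replace=False)]
        bb = b if len(b) == m else b[rng.choice(len(b), m, replace=False)]
        means[i] = _nn_mean(aa, bb, min_pair_um)
    return NNResult(class_pair, float(np.nanmean(means)), float("nan"),
                    float("nan"), m, means)


def label_permutation_reference(
    all_points,
    sizes: tuple[int, int],
    n_perm: int = 1000,
    min_pair_um: float = DEFAULT_MIN_PAIR_UM,
    seed: int = 0,
) -> float:
    """Reference NN distance from random relabelings of the full population.

    Each permutation draws disjoint pseudo-A and pseudo-B sets of the matched
    sizes from all recorded cells and computes the same size-matched NN
    statistic; the reference is the mean over permutations.
    """
    xy = _as_xy(all_points)
    na, nb = sizes
    if len(xy) < na + nb:
        raise ValueError("population smaller than the two class sizes combined")
    rng = spawn_seed(seed, 7)
    m = min(na, nb)
    vals = np.empty(n_perm)
    for i in range(n_perm):
        pick = rng.choice(len(xy), na + nb, replace=False)
        pa, pb = xy[pick[:na]], xy[pick[na:]]
        if na > m:
            pa = pa[rng.choice(na, m, replace=False)]
        if nb > m:
            pb = pb[rng.choice(nb, m, replace=False)]
        vals[i] = _nn_mean(pa, pb, min_pair_um)
    return float(np.nanmean(vals))


def interclass_analysis(
    points: pd.DataFrame,
    class_a: str,
    class_b: str,
    label_col: str = "label",
    min_starters: int = 5,
    min_pair_um: float = DEFAULT_MIN_PAIR_UM,
    n_subsamples: int = 100,
    n_perm: int = 200,
    seed: int = 0,
) -> NNResult:
    """Normalized interclass NN statistic for one session table.

    ``points`` carries anat_x_um/anat_y_um, a class label column, and region;
    the reference permutes labels over *all* rows (the whole recorded
    population), matching the class sizes.
    """
    a = points[points[label_col] == class_a]
    b = points[points[label_col] == class_b]
    res = interclass_nn(a, b, min_starters, min_pair_um, n_subsamples, seed,
                        class_pair=(class_a, class_b))
    ref = label_permutation_reference(points, (len(a), len(b)), n_perm, min_pair_um, seed)
    res.reference_mean_um = ref
    res.normalized = float(res.data_mean_um / ref) if ref > 0 else float("nan")
    return res


def inter_intra_ratio(
    points_a,
    points_b,
    min_starters: int = 5,
    min_pair_um: float = DEFAULT_MIN_PAIR_UM,
    n_subsamples: int = 100,
    seed: int = 0,
) -> float:
    """Mean interclass NN distance over the pooled within-class NN distance.

    Both parts are size-matched to the smaller class; > 1 means the classes
    sit farther from each other than cells of the same class do.
    """
    a, b = _as_xy(points_a), _as_xy(points_b)
    if len(a) < min_starters or len(b) < min_starters:
        raise ValueError(f"both classes need >= {min_starters} cells")
    rng = spawn_seed(seed, 8)
    m = min(len(a), len(b))
    inter = np.empty(n_subsamples)
    intra = np.empty(n_subsamples)
    for i in range(n_subsamples):
        aa = a if len(a) == m else a[rng.choice(len(a), m, replace=False)]
        bb = b if len(b) == m else b[rng.choice(len(b), m, replace=False)]
        inter[i] = _nn_mean(aa, bb, min_pair_um)
        wa = _nn_mean(aa, aa, min_pair_um, same_set=True)
        wb = _nn_mean(bb, bb, min_pair_um, same_set=True)
        intra[i] = np.nanmean([wa, wb])
    return float(np.nanmean(inter) / np.nanmean(intra))


@dataclass
class ClusteringResult:
    cls: str
    k: int
    starter_norm: float            # < 1 => starters cluster
    ref_norm: float
    starter_um: float
    ref_um: float
    all_um: float
    n_starters: int


def _knn_group_mean(xy: np.ndarray, k: int) -> float:
    """Average over cells of the mean distance to their k nearest groupmates."""
    if k >= len(xy):
        raise ValueError("k must be below the group size")
    tree = cKDTree(xy)
    d, _ = tree.query(xy, k=k + 1)
    return float(d[:, 1:].mean())


def withinclass_clustering(
    starters,
    nonstarters,
    all_points,
    k: int = 5,
    min_starters: int = 15,
    n_subsamples: int = 100,
    seed: int = 0,
    cls: str = "",
) -> ClusteringResult:
    """kNN-group statistic for one class: Starter vs Ref vs All.

    The starter group's per-cell mean distance to its ``k`` nearest starters
    is compared with the same statistic on size-matched random subsets of the
    non-starter cells (Ref) and of all cells (All); both normalized to All.
    """
    s = _as_xy(starters)
    ns = _as_xy(nonstarters)
    al = _as_xy(all_points)
    if len(s) < min_starters:
        raise ValueError(f"need >= {min_starters} starter cells (got {len(s)})")
    if k < 1 or k >= len(s):
        raise ValueError("k must be in [1, group size)")
    rng = spawn_seed(seed, 9)
    m = len(s)
    starter_val = _knn_group_mean(s, k)

    def subsampled(pool):
        if len(pool) < m:
            return float("nan")
        vals = np.empty(n_subsamples)
        for i in range(n_subsamples):
            vals[i] = _knn_group_mean(pool[rng.choice(len(pool), m, replace=False)], k)
        return float(vals.mean())

    ref_val = subsampled(ns)
    all_val = subsampled(al)
    return ClusteringResult(cls, k, starter_val / all_val, ref_val / all_val,
                            starter_val, ref_val, all_val, m)


def pairwise_distance_stat(
    starters,
    all_points,
    n_subsamples: int = 100,
    seed: int = 0,
) -> float:
    """Median pairwise distance among starters, normalized to random subsets.

    The alternative clustering statistic: the median over all starter-pair
    distances divided by the mean of the same statistic on size-matched
    random subsets of the full population.
    """
    s = _as_xy(starters)
    al = _as_xy(all_points)
    if len(s) < 2:
        raise ValueError("need at least two starter cells")
    rng = spawn_seed(seed, 10)

    def med_pd(xy):
        d = [np.hypot(*(xy[i] - xy[j])) for i, j in combinations(range(len(xy)), 2)]
        return float(np.median(d))

    obs = med_pd(s)
    refs = np.empty(n_subsamples)
    for i in range(n_subsamples):
        refs[i] = med_pd(al[rng.choice(len(al), len(s), replace=False)])
    return float(obs / refs.mean())
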