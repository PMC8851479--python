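"""Composite-FOV alignment, topographic tuning maps, Moran's I, and
smoothed-map correlations.

Sessions are aligned into one anatomical coordinate frame with a similarity
transform fit to landmark pairs (quality-checked with SSIM).  Each cell's
tuning score is binned at its soma position; projecting over sessions gives
a topographic tuning map per score.  Global structure is measured with
Moran's I against a null that scrambles the score-to-cell (ROI) assignment
while keeping positions fixed — a salt-and-pepper organization.  Pairwise
territory relationships are Pearson correlations of smoothed maps against
the same scramble null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import transform as sktransform
from skimage.metrics import structural_similarity

from ._util import nan_gaussian_smooth, pearson_pairwise, spawn_seed

DEFAULT_BIN_UM = 20.0


# ---------------------------------------------------------------------------
# FOV alignment
# ---------------------------------------------------------------------------


@dataclass
class FOVTransform:
    scale: float
    rotation_deg: float
    translation: tuple[float, float]
    residual_rms: float
    ssim: float                    # NaN when no images supplied
    tform: sktransform.SimilarityTransform

    def apply(self, points_xy: np.ndarray) -> np.ndarray:
        """Map moving-frame coordinates into the reference frame."""
        return self.tform(np.asarray(points_xy, float).reshape(-1, 2))


def fit_fov_transform(
    landmarks_ref: np.ndarray,
    landmarks_moving: np.ndarray,
    image_ref: np.ndarray | None = None,
    image_moving: np.ndarray | None = None,
) -> FOVTransform:
    """Least-squares similarity transform (scale, rotation, translation).

    Needs at least three non-collinear landmark pairs.  When mean images are
    supplied, the moving image is warped into the reference frame and SSIM
    against the reference is reported as alignment quality.
    """
    ref = np.asarray(landmarks_ref, float).reshape(-1, 2)
    mov = np.asarray(landmarks_moving, float).reshape(-1, 2)
    if len(ref) != len(mov) or len(ref) < 3:
        raise ValueError("need >= 3 landmark pairs of equal count")
    centered = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise ValueError("landmarks are collinear; similarity fit is degenerate")
    if hasattr(sktransform.SimilarityTransform, "from_estimate"):
        tf = sktransform.SimilarityTransform.from_estimate(mov, ref)
        if not tf:
            raise ValueError("similarity transform estimation failed")
    else:  # scikit-image < 0.26
        tf = sktransform.SimilarityTransform()
        if not tf.estimate(mov, ref):
            raise ValueError("similarity transform estimation failed")
    resid = tf(mov) - ref
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    ssim = float("nan")
    if image_ref is not None and image_moving is not None:
        warped = sktransform.warp(
            np.asarray(image_moving, float), tf.inverse,
            output_shape=np.asarray(image_ref).shape, preserve_range=True,
        )
        rng_val = float(np.ptp(image_ref)) or 1.0
        ssim = float(structural_similarity(np.asarray(image_ref, float), warped,
                                           data_range=rng_val))
    return FOVTransform(float(tf.scale), float(np.degrees(tf.rotation)),
                        (float(tf.translation[0]), float(tf.translation[1])), rms, ssim, tf)


# ---------------------------------------------------------------------------
# topographic tuning maps
# ---------------------------------------------------------------------------


@dataclass
class TopographicMap:
    values: np.ndarray             # [ny, nx], NaN where no cells fell in a bin
    counts: np.ndarray
    bin_um: float
    origin: tuple[float, float]    # (x0, y0) of the lower-left bin edge


def topographic_map(
    xy_um: np.ndarray,
    values: np.ndarray,
    bin_um: float = DEFAULT_BIN_UM,
    extent: tuple[float, float, float, float] | None = None,
    agg: str = "mean",
) -> TopographicMap:
    """Bin per-cell tuning values on an anatomical grid (pooled over sessions).

    ``extent`` = (x0, x1, y0, y1) in µm; default hugs the data.  Aggregator is
    the per-bin mean (``max`` available).  Bins without cells are missing.
    """
    xy = np.asarray(xy_um, float).reshape(-1, 2)
    v = np.asarray(values, float)
    keep = np.isfinite(v) & np.all(np.isfinite(xy), axis=1)
    xy, v = xy[keep], v[keep]
    if len(v) == 0:
        return TopographicMap(np.full((1, 1), np.nan), np.zeros((1, 1), int), bin_um, (0.0, 0.0))
    if extent is None:
        x0, x1 = xy[:, 0].min(), xy[:, 0].max() + 1e-9
        y0, y1 = xy[:, 1].min(), xy[:, 1].max() + 1e-9
    else:
        x0, x1, y0, y1 = extent
    nx = max(int(np.ceil((x1 - x0) / bin_um)), 1)
    ny = max(int(np.ceil((y1 - y0) / bin_um)), 1)
    ix = np.clip(((xy[:, 0] - x0) / bin_um).astype(int), 0, nx - 1)
    iy = np.clip(((xy[:, 1] - y0) / bin_um).astype(int), 0, ny - 1)
    flat = iy * nx + ix
    counts = np.bincount(flat, minlength=ny * nx)
    out = np.full(ny * nx, np.nan)
    occ = counts > 0
    if agg == "mean":
        sums = np.bincount(flat, weights=v, minlength=ny * nx)
        out[occ] = sums[occ] / counts[occ]
    elif agg == "max":
        np.maximum.at(out := np.full(ny * nx, -np.inf), flat, v)
        out[~occ] = np.nan
    else:
        raise ValueError("agg must be 'mean' or 'max'")
    return TopographicMap(out.reshape(ny, nx), counts.reshape(ny, nx), bin_um, (float(x0), float(y0)))


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------


def _grid_adjacency(mask: np.ndarray, scheme: str = "queen") -> np.ndarray:
    """Binary contiguity matrix over the defined bins of a 2-D mask."""
    ny, nx = mask.shape
    idx = -np.ones((ny, nx), int)
    ys, xs = np.nonzero(mask)
    idx[ys, xs] = np.arange(len(ys))
    n = len(ys)
    w = np.zeros((n, n))
    if scheme == "rook":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif scheme == "queen":
        offsets = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    else:
        raise ValueError("scheme must be 'rook' or 'queen'")
    for y, x in zip(ys, xs):
        for dy, dx in offsets:
            yy, xx = y + dy, x + dx
            if 0 <= yy < ny and 0 <= xx < nx and mask[yy, xx]:
                w[idx[y, x], idx[yy, xx]] = 1.0
    return w


def morans_i(
    values: np.ndarray | TopographicMap,
    weights: np.ndarray | None = None,
    scheme: str = "queen",
    min_bins: int = 10,
) -> float:
    """Global spatial autocorrelation I over the defined bins of a map.

    I = (N/W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2.
    An explicit ``weights`` matrix (ordered like np.nonzero of the defined
    mask) overrides the grid contiguity ``scheme``.  Missing when the map has
    fewer than ``min_bins`` defined bins (unless weights are explicit) or
    zero variance.
    """
    m = values.values if isinstance(values, TopographicMap) else np.asarray(values, float)
    mask = np.isfinite(m)
    x = m[mask]
    if weights is None:
        if mask.sum() < min_bins:
            raise ValueError(f"need >= {min_bins} defined bins")
        weights = _grid_adjacency(mask, scheme)
    w = np.asarray(weights, float)
    if w.shape != (len(x), len(x)):
        raise ValueError("weights shape does not match the defined bins")
    xd = x - x.mean()
    denom = float(np.sum(xd**2))
    w_sum = float(w.sum())
    if denom == 0 or w_sum == 0:
        return float("nan")
    return float(len(x) / w_sum * (xd @ w @ xd) / denom)


@dataclass
class ScrambleNull:
    observed: float
    samples: np.ndarray
    p95: float
    p99: float


def morans_scramble_null(
    xy_um: np.ndarray,
    values: np.ndarray,
    bin_um: float = DEFAULT_BIN_UM,
    n_perm: int = 1000,
    seed: int = 0,
    scheme: str = "queen",
    extent=None,
) -> ScrambleNull:
    """Moran's I null from scrambling score-to-cell assignments.

    Positions stay fixed; scores are permuted across all cells, the map is
    rebuilt and I recomputed — the salt-and-pepper control for territory
    structure.
    """
    tm = topographic_map(xy_um, values, bin_um, extent)
    obs = morans_i(tm, scheme=scheme)
    rng = spawn_seed(seed, 12)
    v = np.asarray(values, float)
    samples = np.empty(n_perm)
    for i in range(n_perm):
        perm_map = topographic_map(xy_um, rng.permutation(v), bin_um, extent)
        try:
            samples[i] = morans_i(perm_map, scheme=scheme)
        except ValueError:
            samples[i] = np.nan
    finite = samples[np.isfinite(samples)]
    return ScrambleNull(obs, samples, float(np.percentile(finite, 95)),
                        float(np.percentile(finite, 99)))


# ---------------------------------------------------------------------------
# smoothed-map correlations
# ---------------------------------------------------------------------------


@dataclass
class MapComparison:
    property_pair: tuple[str, str]
    r: float
    null_samples: np.ndarray
    delta: float                   # r - median(null)
    null_p05: float
    null_p95: float


def map_correlation(map_a: TopographicMap, map_b: TopographicMap, sigma_bins: float = 2.0) -> float:
    """Pearson r between two smoothed maps over jointly defined bins."""
    if map_a.values.shape != map_b.values.shape:
        raise ValueError("maps must share the bin grid")
    a = nan_gaussian_smooth(map_a.values, sigma_bins)
    b = nan_gaussian_smooth(map_b.values, sigma_bins)
    return pearson_pairwise(a, b, min_n=10)


def map_comparison(
    xy_um: np.ndarray,
    values_a: np.ndarray,
    values_b: np.ndarray,
    bin_um: float = DEFAULT_BIN_UM,
    sigma_bins: float = 2.0,
    n_perm: int = 1000,
    seed: int = 0,
    extent=None,
    property_pair: tuple[str, str] = ("A", "B"),
) -> MapComparison:
    """Smoothed-map Pearson r with its ROI-scramble null and delta.

    The null permutes each property's scores across cells independently
    (positions fixed), rebuilds and smooths both maps, and recorrelates.
    delta = r - median(null); below zero means the two properties occupy
    anticorrelated territories beyond chance.
    """
    if extent is None:
        xy = np.asarray(xy_um, float)
        extent = (xy[:, 0].min(), xy[:, 0].max() + 1e-9, xy[:, 1].min(), xy[:, 1].max() + 1e-9)
    ma = topographic_map(xy_um, values_a, bin_um, extent)
    mb = topographic_map(xy_um, values_b, bin_um, extent)
    r = map_correlation(ma, mb, sigma_bins)
    rng = spawn_seed(seed, 13)
    va = np.asarray(values_a, float)
    vb = np.asarray(values_b, float)
    samples = np.empty(n_perm)
    for i in range(n_perm):
        pa = topographic_map(xy_um, rng.permutation(va), bin_um, extent)
        pb = topographic_map(xy_um, rng.permutation(vb), bin_um, extent)
        samples[i] = map_correlation(pa, pb, sigma_bins)
    finite = samples[np.isfinite(samples)]
    return MapComparison(property_pair, r, samples, float(r - np.median(finite)),
                         float(np.percentile(finite, 5)), float(np.percentile(finite, 95)))


def discrimination_ratio(comparisons: list[MapComparison], hi: float = 95.0, lo: float = 5.0) -> float:
    """(N above the hi null percentile - N below the lo percentile) / N animals.

    -1 when every animal's map correlation sits below its own null's lower
    cutoff (stable anticorrelated territories), +1 for the reverse.
    """
    if not comparisons:
        raise ValueError("need at least one per-animal comparison")
    above = below = 0
    for c in comparisons:
        finite = c.null_samples[np.isfinite(c.null_samples)]
        if c.r > np.percentile(finite, hi):
            above += 1
        elif c.r < np.percentile(finite, lo):
            below += 1
    return float((above - below) / len(comparisons))
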