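"""Occupancy, tuning maps/curves, and spatial-directional scores.

Implements the standard open-field battery for calcium-imaging data with
deconvolved event amplitudes: occupancy-normalized rate maps, spatial
autocorrelograms, the rotational grid score, a Solstad-style border score,
head-direction tuning with mean vector length (MVL), object-vector polar
maps with the cross-session OV score, Skaggs spatial information, and an
event-triggered signal-to-noise filter.

Conventions: spatial bins default to 2.5 cm, 60 head-direction bins (6 deg),
rate-map smoothing sigma 1.5 bins, speed filter 2.5 cm/s.  Unvisited bins
are missing (NaN), never zero; correlations use pairwise-complete bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage, signal
from skimage import measure

from ._util import nan_gaussian_smooth, pearson_pairwise
from .synthio import ArenaSpec, Trajectory

DEFAULT_SPEED_MIN_CMS = 2.5
DEFAULT_SMOOTH_SIGMA_BINS = 1.5
DEFAULT_N_DIR_BINS = 60
SNR_CAP = 1e6


class EmptyOccupancyError(ValueError):
    """Speed filtering removed every frame."""


# ---------------------------------------------------------------------------
# occupancy and rate maps
# ---------------------------------------------------------------------------


@dataclass
class OccupancyMap:
    seconds: np.ndarray            # [ny, nx] dwell time per bin, speed-filtered
    visited: np.ndarray            # bool mask
    exploration_ratio: float
    exploration_sd: float
    arena: ArenaSpec
    total_s: float


@dataclass
class RateMap:
    rate: np.ndarray               # events/s, NaN where unvisited
    arena: ArenaSpec
    smoothing_sigma_bins: float


def _bin_indices(traj: Trajectory, arena: ArenaSpec, frame_mask: np.ndarray):
    nb = arena.n_bins
    ix = np.clip((traj.x_cm[frame_mask] / arena.bin_cm).astype(int), 0, nb - 1)
    iy = np.clip((traj.y_cm[frame_mask] / arena.bin_cm).astype(int), 0, nb - 1)
    return iy * nb + ix


def _speed_mask(traj: Trajectory, speed_min_cms: float) -> np.ndarray:
    if speed_min_cms <= 0:
        return np.ones(traj.n_frames, dtype=bool)
    return traj.speed_cms() >= speed_min_cms


def compute_occupancy(
    traj: Trajectory,
    arena: ArenaSpec | None = None,
    speed_min_cms: float = DEFAULT_SPEED_MIN_CMS,
    min_dwell_s: float = 0.0,
) -> OccupancyMap:
    """Dwell time per spatial bin after excluding slow (resting) frames.

    ``exploration_ratio`` is the fraction of bins visited longer than
    ``min_dwell_s``; ``exploration_sd`` is the coefficient of variation of
    per-bin dwell time over all bins (sd divided by mean).
    """
    arena = arena or ArenaSpec()
    keep = _speed_mask(traj, speed_min_cms)
    if not keep.any():
        raise EmptyOccupancyError("speed filter removed all frames")
    nb = arena.n_bins
    flat = np.bincount(_bin_indices(traj, arena, keep), minlength=nb * nb) * traj.dt
    seconds = flat.reshape(nb, nb)
    visited = seconds > min_dwell_s
    ratio = float(visited.sum() / visited.size)
    mean = seconds.mean()
    sd = float(seconds.std() / mean) if mean > 0 else float("nan")
    return OccupancyMap(seconds, visited, ratio, sd, arena, float(seconds.sum()))


def compute_ratemap(
    events: np.ndarray,
    traj: Trajectory,
    arena: ArenaSpec | None = None,
    smoothing_sigma_bins: float = DEFAULT_SMOOTH_SIGMA_BINS,
    speed_min_cms: float = DEFAULT_SPEED_MIN_CMS,
) -> RateMap:
    """Occupancy-normalized spatial tuning map.

    Event amplitude and dwell time are binned separately, both smoothed with
    the same Gaussian kernel, then divided; bins never visited stay NaN.
    """
    arena = arena or ArenaSpec()
    if len(events) != traj.n_frames:
        raise ValueError("events and trajectory lengths differ")
    keep = _speed_mask(traj, speed_min_cms)
    if not keep.any():
        raise EmptyOccupancyError("speed filter removed all frames")
    nb = arena.n_bins
    idx = _bin_indices(traj, arena, keep)
    amp = np.bincount(idx, weights=events[keep], minlength=nb * nb).reshape(nb, nb)
    occ = (np.bincount(idx, minlength=nb * nb) * traj.dt).reshape(nb, nb)
    visited = occ > 0
    if smoothing_sigma_bins > 0:
        amp = ndimage.gaussian_filter(amp, smoothing_sigma_bins, mode="constant")
        occ = ndimage.gaussian_filter(occ, smoothing_sigma_bins, mode="constant")
    rate = np.full((nb, nb), np.nan)
    good = visited & (occ > 1e-12)
    rate[good] = amp[good] / occ[good]
    return RateMap(rate, arena, smoothing_sigma_bins)


# ---------------------------------------------------------------------------
# spatial autocorrelogram and grid score
# ---------------------------------------------------------------------------


@dataclass
class Autocorrelogram:
    values: np.ndarray             # [(2ny-1), (2nx-1)], NaN where undefined
    n_overlap: np.ndarray


def spatial_autocorrelogram(ratemap: RateMap | np.ndarray, min_overlap: int = 20) -> Autocorrelogram:
    """Pearson correlation of a map with itself at every integer offset.

    Only bins defined at both positions enter each offset's correlation;
    offsets with fewer than ``min_overlap`` overlapping bins are missing.
    Computed with FFT cross-correlations of the masked sums.
    """
    m = ratemap.rate if isinstance(ratemap, RateMap) else np.asarray(ratemap, float)
    mask = np.isfinite(m)
    if mask.sum() < min_overlap:
        raise ValueError("too few defined bins")
    x = np.where(mask, m, 0.0)
    mf = mask.astype(float)

    def xcorr(a, b):
        return signal.fftconvolve(a, b[::-1, ::-1], mode="full")

    n = xcorr(mf, mf)
    sx = xcorr(x, mf)
    sy = xcorr(mf, x)
    sxy = xcorr(x, x)
    sxx = xcorr(x * x, mf)
    syy = xcorr(mf, x * x)
    n = np.round(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        r = cov / np.sqrt(np.maximum(varx, 0) * np.maximum(vary, 0))
    bad = (n < min_overlap) | (varx <= 1e-8 * np.maximum(n, 1) ** 2) | (vary <= 1e-8 * np.maximum(n, 1) ** 2)
    r[bad] = np.nan
    r = np.clip(r, -1.0, 1.0)
    # zero offset is exactly 1 by definition
    cy, cx = (r.shape[0] - 1) // 2, (r.shape[1] - 1) // 2
    if np.isfinite(r[cy, cx]):
        r[cy, cx] = 1.0
    return Autocorrelogram(r, n.astype(int))


def grid_autocorrelogram(ratemap: RateMap | np.ndarray, min_overlap: int = 20) -> Autocorrelogram:
    """Autocorrelogram for gridness: the map is first masked to its inscribed disk.

    Per-offset Pearson correlations on a square window carry a four-fold
    anisotropy from the window geometry itself (corr90 of even an isotropic
    map is ~1), which would bias the rotation-based grid score.  Restricting
    the map to the inscribed circle makes the overlap geometry
    rotation-symmetric, so isotropic maps score near zero.
    """
    m = (ratemap.rate if isinstance(ratemap, RateMap) else np.asarray(ratemap, float)).copy()
    ny, nx = m.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    rr = np.hypot(yy - (ny - 1) / 2, xx - (nx - 1) / 2)
    m[rr > min(ny, nx) / 2] = np.nan
    return spatial_autocorrelogram(m, min_overlap)


@lru_cache(maxsize=64)
def _rotation_coords(shape: tuple[int, int], angle_deg: float) -> np.ndarray:
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    a = np.deg2rad(angle_deg)
    dy, dx = yy - cy, xx - cx
    sy = cy + np.cos(a) * dy - np.sin(a) * dx
    sx = cx + np.sin(a) * dy + np.cos(a) * dx
    return np.array([sy, sx])


def _rotate_nan(values: np.ndarray, angle_deg: float) -> np.ndarray:
    coords = _rotation_coords(values.shape, float(angle_deg))
    valid = np.isfinite(values).astype(float)
    vals = ndimage.map_coordinates(np.nan_to_num(values), coords, order=1, cval=0.0)
    wts = ndimage.map_coordinates(valid, coords, order=1, cval=0.0)
    out = np.full(values.shape, np.nan)
    ok = wts > 0.99
    out[ok] = vals[ok] / wts[ok]
    return out


def _annulus_radii(ac: np.ndarray) -> tuple[float, float]:
    """Inner radius from the central peak extent, outer from the six nearest peaks."""
    h, w = ac.shape
    cy, cx = (h - 1) // 2, (w - 1) // 2
    half = min(cy, cx)
    filled = np.nan_to_num(ac, nan=-2.0)
    # central peak: contiguous region of correlation >= 0.3 around the center
    core = measure.label(filled >= 0.3)
    lab = core[cy, cx]
    yy, xx = np.mgrid[0:h, 0:w]
    rr = np.hypot(yy - cy, xx - cx)
    inner = float(rr[core == lab].max()) + 1.0 if lab > 0 else 2.0
    inner = min(inner, half - 2.0)

    # surrounding peaks: strict local maxima above zero correlation
    is_peak = (filled == ndimage.maximum_filter(filled, size=5)) & (filled > 0.0)
    d = rr[is_peak]
    d = np.sort(d[d > inner])
    # rotation correlations need the ring defined at every orientation: cap at
    # the largest radius still >= 95% defined all-around
    finite = np.isfinite(ac)
    r_def = float(half)
    for r in range(int(half), 1, -1):
        disk = rr <= r
        if finite[disk].mean() >= 0.95:
            r_def = float(r)
            break
    if len(d) >= 6:
        outer = 1.25 * float(np.median(d[:6]))
    else:
        outer = r_def
    outer = min(outer, r_def, float(half))
    if outer <= inner + 1.0:
        outer = r_def
        inner = min(inner, outer - 2.0)
    return max(inner, 1.0), outer


def grid_score(ac: Autocorrelogram | np.ndarray) -> float:
    """Rotational-symmetry statistic of the spatial autocorrelogram.

    The annulus between the central peak and the ring of surrounding peaks is
    correlated with itself rotated by 30/60/90/120/150 deg;
    GS = min(corr60, corr120) - max(corr30, corr90, corr150).  Positive for
    60-deg-periodic (hexagonal) structure, negative for 90-deg-periodic.
    """
    a = ac.values if isinstance(ac, Autocorrelogram) else np.asarray(ac, float)
    h, w = a.shape
    cy, cx = (h - 1) // 2, (w - 1) // 2
    if not np.isfinite(a[cy, cx]):
        return float("nan")
    inner, outer = _annulus_radii(a)
    yy, xx = np.mgrid[0:h, 0:w]
    rr = np.hypot(yy - cy, xx - cx)
    ring = (rr > inner) & (rr <= outer) & np.isfinite(a)
    if ring.sum() < 20:
        return float("nan")
    ry, rx = np.nonzero(ring)
    ring_vals = a[ry, rx]
    valid = np.isfinite(a).astype(float)
    filled = np.nan_to_num(a)
    corrs = {}
    dy, dx = ry - cy, rx - cx
    for ang in (30, 60, 90, 120, 150):
        t = np.deg2rad(ang)
        sy = cy + np.cos(t) * dy - np.sin(t) * dx
        sx = cx + np.sin(t) * dy + np.cos(t) * dx
        rot = ndimage.map_coordinates(filled, [sy, sx], order=1, cval=0.0)
        wts = ndimage.map_coordinates(valid, [sy, sx], order=1, cval=0.0)
        pair = np.where(wts > 0.99, rot / np.maximum(wts, 1e-12), np.nan)
        corrs[ang] = pearson_pairwise(ring_vals, pair, min_n=20)
    if any(not np.isfinite(v) for v in corrs.values()):
        return float("nan")
    return float(min(corrs[60], corrs[120]) - max(corrs[30], corrs[90], corrs[150]))


# ---------------------------------------------------------------------------
# border score
# ---------------------------------------------------------------------------


def border_score(
    ratemap: RateMap | np.ndarray,
    field_threshold_frac: float = 0.3,
    min_field_bins: int = 20,
) -> float:
    """Solstad-style border score, in [-1, 1].

    Fields are connected components of bins above ``field_threshold_frac`` of
    the map maximum with at least ``min_field_bins`` bins.  cM is the largest
    fraction of any single wall covered by a single field; dm is the
    rate-weighted mean distance of all field bins to their nearest wall,
    normalized by half the arena side.  BS = (cM - dm)/(cM + dm).
    """
    m = ratemap.rate if isinstance(ratemap, RateMap) else np.asarray(ratemap, float)
    defined = np.isfinite(m)
    if defined.sum() < 0.5 * m.size:
        return float("nan")
    rate = np.where(defined, m, 0.0)
    peak = rate.max()
    if peak <= 0:
        return float("nan")
    labels = measure.label(rate >= field_threshold_frac * peak)
    sizes = np.bincount(labels.ravel())
    field_ids = [i for i in range(1, len(sizes)) if sizes[i] >= min_field_bins]
    if not field_ids:
        return float("nan")
    ny, nx = m.shape
    walls = [labels[:, 0], labels[:, -1], labels[0, :], labels[-1, :]]
    c_m = 0.0
    for wall in walls:
        for fid in field_ids:
            c_m = max(c_m, float(np.mean(wall == fid)))
    in_field = np.isin(labels, field_ids)
    yy, xx = np.mgrid[0:ny, 0:nx]
    dist = np.minimum.reduce([xx, nx - 1 - xx, yy, ny - 1 - yy]).astype(float)
    wts = rate[in_field]
    d_m = float(np.average(dist[in_field], weights=wts) / (min(nx, ny) / 2.0))
    if c_m + d_m == 0:
        return float("nan")
    return float((c_m - d_m) / (c_m + d_m))


# ---------------------------------------------------------------------------
# head-direction tuning
# ---------------------------------------------------------------------------


@dataclass
class HDTuning:
    bin_centers_deg: np.ndarray
    occ_s: np.ndarray
    rate: np.ndarray               # events/s per direction bin, NaN if unoccupied


def hd_tuning(
    events: np.ndarray,
    traj: Trajectory,
    n_dir_bins: int = DEFAULT_N_DIR_BINS,
    speed_min_cms: float = DEFAULT_SPEED_MIN_CMS,
    smoothing_sigma_bins: float = 1.0,
) -> HDTuning:
    """Directional tuning curve: amplitude per HD bin over dwell time per bin.

    Smoothing is circular (wrapped Gaussian, sigma in direction bins).
    Raises if more than half of the direction bins were never occupied.
    """
    if len(events) != traj.n_frames:
        raise ValueError("events and trajectory lengths differ")
    keep = _speed_mask(traj, speed_min_cms)
    idx = np.clip((traj.hd_deg[keep] / (360.0 / n_dir_bins)).astype(int), 0, n_dir_bins - 1)
    occ = np.bincount(idx, minlength=n_dir_bins) * traj.dt
    amp = np.bincount(idx, weights=events[keep], minlength=n_dir_bins)
    if np.mean(occ == 0) > 0.5:
        raise ValueError("more than half of the direction bins are unoccupied")
    if smoothing_sigma_bins > 0:
        occ_s = ndimage.gaussian_filter1d(occ, smoothing_sigma_bins, mode="wrap")
        amp_s = ndimage.gaussian_filter1d(amp, smoothing_sigma_bins, mode="wrap")
    else:
        occ_s, amp_s = occ, amp
    rate = np.full(n_dir_bins, np.nan)
    good = occ_s > 1e-12
    rate[good] = amp_s[good] / occ_s[good]
    centers = (np.arange(n_dir_bins) + 0.5) * 360.0 / n_dir_bins
    return HDTuning(centers, occ, rate)


def mvl(h: HDTuning) -> float:
    """Mean vector length of the tuning curve, |sum r e^{i theta}| / sum r."""
    good = np.isfinite(h.rate)
    r = h.rate[good]
    if r.sum() <= 0:
        return float("nan")
    th = np.deg2rad(h.bin_centers_deg[good])
    return float(np.abs(np.sum(r * np.exp(1j * th))) / np.sum(r))


# ---------------------------------------------------------------------------
# object-vector maps
# ---------------------------------------------------------------------------


@dataclass
class ObjectVectorMap:
    rate: np.ndarray               # [n_dist_bins, n_dir_bins], NaN unoccupied
    dist_bin_cm: float
    n_dir_bins: int


def object_vector_map(
    events: np.ndarray,
    traj: Trajectory,
    object_xy: tuple[float, float],
    arena: ArenaSpec | None = None,
    dist_bin_cm: float | None = None,
    n_dir_bins: int = DEFAULT_N_DIR_BINS,
    speed_min_cms: float = DEFAULT_SPEED_MIN_CMS,
    smoothing_sigma_bins: float = DEFAULT_SMOOTH_SIGMA_BINS,
) -> ObjectVectorMap:
    """Polar tuning map in object-centered coordinates.

    Each frame is assigned a (distance, allocentric angle) bin of the animal's
    position relative to the object; rate = amplitude / dwell time per bin.
    Smoothing (same sigma for both axes) wraps around the angle axis.
    """
    arena = arena or ArenaSpec()
    if len(events) != traj.n_frames:
        raise ValueError("events and trajectory lengths differ")
    dist_bin_cm = dist_bin_cm or arena.bin_cm
    keep = _speed_mask(traj, speed_min_cms)
    dx = traj.x_cm[keep] - object_xy[0]
    dy = traj.y_cm[keep] - object_xy[1]
    d = np.hypot(dx, dy)
    ang = np.mod(np.degrees(np.arctan2(dy, dx)), 360.0)
    n_dist = int(np.ceil(arena.side_cm * np.sqrt(2) / dist_bin_cm))
    di = np.clip((d / dist_bin_cm).astype(int), 0, n_dist - 1)
    ai = np.clip((ang / (360.0 / n_dir_bins)).astype(int), 0, n_dir_bins - 1)
    flat = di * n_dir_bins + ai
    occ = (np.bincount(flat, minlength=n_dist * n_dir_bins) * traj.dt
           ).reshape(n_dist, n_dir_bins)
    amp = np.bincount(flat, weights=events[keep], minlength=n_dist * n_dir_bins
                      ).reshape(n_dist, n_dir_bins)
    visited = occ > 0
    if smoothing_sigma_bins > 0:
        amp = ndimage.gaussian_filter(amp, smoothing_sigma_bins,
                                      mode=("constant", "wrap"))
        occ = ndimage.gaussian_filter(occ, smoothing_sigma_bins,
                                      mode=("constant", "wrap"))
    rate = np.full((n_dist, n_dir_bins), np.nan)
    good = visited & (occ > 1e-12)
    rate[good] = amp[good] / occ[good]
    return ObjectVectorMap(rate, dist_bin_cm, n_dir_bins)


def ov_score(map1: ObjectVectorMap, map2: ObjectVectorMap, min_joint_bins: int = 100) -> float:
    """Pearson correlation of two sessions' polar maps over jointly defined bins.

    High when the field keeps its distance and direction relative to the
    object across the two object sessions.  Missing if fewer than
    ``min_joint_bins`` bins are defined in both.
    """
    a, b = map1.rate, map2.rate
    if a.shape != b.shape:
        raise ValueError("polar maps must share a shape")
    joint = np.isfinite(a) & np.isfinite(b)
    if joint.sum() < min_joint_bins:
        return float("nan")
    return pearson_pairwise(a, b, min_n=min_joint_bins)


# ---------------------------------------------------------------------------
# spatial information and SNR
# ---------------------------------------------------------------------------


def spatial_information(ratemap: RateMap | np.ndarray, occupancy: OccupancyMap | np.ndarray) -> float:
    """Skaggs information content in bits per event.

    I = sum_i p_i (lam_i / lam_bar) log2(lam_i / lam_bar) over visited bins,
    with p_i the occupancy fraction and lam_bar the occupancy-weighted mean
    rate.  Missing when the mean rate is zero.
    """
    rate = ratemap.rate if isinstance(ratemap, RateMap) else np.asarray(ratemap, float)
    occ = occupancy.seconds if isinstance(occupancy, OccupancyMap) else np.asarray(occupancy, float)
    good = np.isfinite(rate) & (occ > 0)
    if not good.any():
        return float("nan")
    p = occ[good] / occ[good].sum()
    lam = rate[good]
    lam_bar = float(np.sum(p * lam))
    if lam_bar <= 0:
        return float("nan")
    ratio = lam / lam_bar
    terms = np.zeros_like(ratio)
    nz = ratio > 0
    terms[nz] = p[nz] * ratio[nz] * np.log2(ratio[nz])
    return float(terms.sum())


def estimate_snr(dff: np.ndarray, events: np.ndarray, fps: float = 7.52) -> float:
    """Peak event-triggered dF/F amplitude over the robust baseline noise sd.

    Baseline frames are those at least one indicator decay away from any
    event; noise sd is 1.4826 x the median absolute deviation there.
    """
    event_frames = events > 0
    if not event_frames.any():
        return 0.0
    reach = max(int(round(2 * 1.5 * fps)), 1)
    near = ndimage.binary_dilation(event_frames, structure=np.ones(2 * reach + 1, bool))
    baseline = dff[~near]
    if len(baseline) < 10:
        baseline = dff[~event_frames]
    med = np.median(baseline) if len(baseline) else 0.0
    noise = 1.4826 * np.median(np.abs(baseline - med)) if len(baseline) else 0.0
    peak = float(np.max(dff[near]) - med)
    if noise <= 0:
        return SNR_CAP if peak > 0 else 0.0
    return float(min(peak / noise, SNR_CAP))


def filter_by_snr(dff: np.ndarray, events: np.ndarray, snr_min: float = 4.0, fps: float = 7.52):
    """Keep/drop decision plus the SNR value; cells with no events are dropped."""
    snr = estimate_snr(dff, events, fps)
    return snr >= snr_min, snr


# ---------------------------------------------------------------------------
# convenience: score a whole session
# ---------------------------------------------------------------------------


def score_cell(
    events: np.ndarray,
    traj: Trajectory,
    arena: ArenaSpec | None = None,
    smoothing_sigma_bins: float = DEFAULT_SMOOTH_SIGMA_BINS,
    speed_min_cms: float = DEFAULT_SPEED_MIN_CMS,
) -> dict:
    """Grid score, border score, MVL, and spatial information for one cell."""
    arena = arena or ArenaSpec()
    rm = compute_ratemap(events, traj, arena, smoothing_sigma_bins, speed_min_cms)
    occ = compute_occupancy(traj, arena, speed_min_cms)
    try:
        gs = grid_score(grid_autocorrelogram(rm))
    except ValueError:
        gs = float("nan")
    bs = border_score(rm)
    try:
        m = mvl(hd_tuning(events, traj, speed_min_cms=speed_min_cms))
    except ValueError:
        m = float("nan")
    si = spatial_information(rm, occ)
    return {"grid_score": gs, "border_score": bs, "mvl": m, "spatial_info": si}
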