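"""Small numerical helpers shared across modules."""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def spawn_seed(seed: int, *keys: int) -> np.random.Generator:
    """Derive an independent generator from a base seed and integer keys."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


def nan_gaussian_smooth(values: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-smooth a 2-D array with missing entries (normalized convolution).

    Undefined (NaN) bins do not contribute to their neighbors and stay NaN
    in the output.
    """
    if sigma <= 0:
        return values.copy()
    mask = np.isfinite(values)
    filled = np.where(mask, values, 0.0)
    num = ndimage.gaussian_filter(filled, sigma, mode="constant")
    den = ndimage.gaussian_filter(mask.astype(float), sigma, mode="constant")
    out = np.full(values.shape, np.nan)
    good = den > 1e-12
    out[good] = num[good] / den[good]
    out[~mask] = np.nan
    return out


def pearson_pairwise(a: np.ndarray, b: np.ndarray, min_n: int = 2) -> float:
    """Pearson correlation over entries defined in both arrays; NaN if degenerate."""
    m = np.isfinite(a) & np.isfinite(b)
    if m.sum() < min_n:
        return float("nan")
    x, y = a[m], b[m]
    sx, sy = x.std(), y.std()
    if sx <= 0 or sy <= 0:
        return float("nan")
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def wrap_deg(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to [0, 360)."""
    return np.mod(angle, 360.0)
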