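"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own implementations: connected
components by explicit flood fill, Gaussian smoothing by dense kernel
summation, and the GTM solve by dense least squares.
"""

from __future__ import annotations

import numpy as np

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def flood_fill_components(mask: np.ndarray, connectivity: int = 26) -> list[set]:
    """All maximal connected components as sets of voxel tuples."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                   (0, 0, 1), (0, 0, -1)]
    elif connectivity == 26:
        offsets = [(dx, dy, dz)
                   for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                   if (dx, dy, dz) != (0, 0, 0)]
    else:
        raise ValueError(connectivity)
    remaining = {tuple(c) for c in np.argwhere(mask)}
    comps = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            cx, cy, cz = frontier.pop()
            for dx, dy, dz in offsets:
                nb = (cx + dx, cy + dy, cz + dz)
                if nb in remaining:
                    remaining.remove(nb)
                    comp.add(nb)
                    frontier.append(nb)
        comps.append(comp)
    return comps


def dense_gaussian_smooth(data: np.ndarray, voxel_size_mm: float,
                          fwhm_mm: float, truncate: float = 4.0) -> np.ndarray:
    """Direct dense separable convolution with zero padding.

    The discrete kernel is a normalized sampled Gaussian truncated at
    ``truncate`` standard deviations, applied by explicit shifted sums.
    """
    data = np.asarray(data, dtype=float)
    sigma = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    out = data
    for axis in range(3):
        acc = np.zeros_like(out)
        padded = np.pad(out, [(radius, radius) if a == axis else (0, 0)
                              for a in range(3)])
        for k, w in enumerate(kernel):
            sl = [slice(None)] * 3
            sl[axis] = slice(k, k + out.shape[axis])
            acc += w * padded[tuple(sl)]
        out = acc
    return out


def lstsq_oracle(omega: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Dense least-squares solution via the normal-equation pseudo-inverse."""
    return np.linalg.pinv(omega) @ np.asarray(t, dtype=float)
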