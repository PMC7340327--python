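"""Shared independent oracles for the test suite.

These deliberately avoid the library code paths they are used to check.
"""

import numpy as np


def grid_search_circ_mean(angles, weights=None, period=360.0, step=0.01):
    """Brute-force circular mean: the angle on a fine grid minimizing the
    weighted mean (1 - cos) distance to the data."""
    angles = np.asarray(angles, dtype=float)
    if weights is None:
        weights = np.ones_like(angles)
    weights = np.asarray(weights, dtype=float)
    grid = np.arange(0.0, period, step)
    scale = 360.0 / period
    diff = np.deg2rad(scale * (grid[:, None] - angles[None, :]))
    cost = (weights[None, :] * (1.0 - np.cos(diff))).sum(axis=1)
    return grid[int(np.argmin(cost))]


def dense_gaussian_derivative(raster, sigma_px, axis):
    """Direct dense correlation with explicitly constructed separable
    Gaussian / Gaussian-derivative kernels (truncated at 3 sigma).

    Response to a unit ramp along ``axis`` is +1 (derivative along
    increasing index).  Returns (out, valid_interior_mask).
    """
    r = int(np.ceil(3.0 * sigma_px))
    u = np.arange(-r, r + 1, dtype=float)
    g = np.exp(-0.5 * (u / sigma_px) ** 2)
    g /= g.sum()
    dg = u * np.exp(-0.5 * (u / sigma_px) ** 2)
    dg /= (u * dg).sum()   # unit response to a unit ramp
    if axis == 1:
        ky, kx = g, dg      # derivative along columns (x)
    else:
        ky, kx = dg, g      # derivative along rows (y)
    kern = np.outer(ky, kx)
    out = np.zeros_like(raster)
    rows, cols = raster.shape
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            w = kern[dy + r, dx + r]
            if w == 0.0:
                continue
            out[r:rows - r, r:cols - r] += w * raster[r + dy:rows - r + dy,
                                                      r + dx:cols - r + dx]
    valid = np.zeros(raster.shape, dtype=bool)
    valid[r:rows - r, r:cols - r] = True
    return out, valid


def weighted_phasor_mean(angles, weights):
    """Direct weighted phasor mean in degrees [0, 360)."""
    z = np.sum(np.asarray(weights) * np.exp(1j * np.deg2rad(np.asarray(angles))))
    return np.rad2deg(np.angle(z)) % 360.0
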