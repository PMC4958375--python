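"""Brute-force numerical-integration oracles for the Gaussian belief updates.

These compute posterior moments and incentive values directly from the
generative-model densities on a dense grid (trapezoidal integration over
mean +/- 10 SD with at least 2001 points per dimension, where truncation
error for Gaussians is negligible), fully independent of the closed-form
conjugate updates they are used to check.
"""

from __future__ import annotations

import numpy as np

N_POINTS = 2001
RANGE_SDS = 10.0


def _grid(anchors: list[float], max_variance: float) -> np.ndarray:
    half = RANGE_SDS * np.sqrt(max_variance)
    lo = min(anchors) - half
    hi = max(anchors) + half
    return np.linspace(lo, hi, N_POINTS)


def _normal_pdf(x: np.ndarray, mean: float | np.ndarray, variance: float) -> np.ndarray:
    return np.exp(-0.5 * (x - mean) ** 2 / variance) / np.sqrt(2 * np.pi * variance)


def _moments(grid: np.ndarray, density: np.ndarray) -> tuple[float, float]:
    z = np.trapezoid(density, grid)
    mean = np.trapezoid(grid * density, grid) / z
    var = np.trapezoid((grid - mean) ** 2 * density, grid) / z
    return float(mean), float(var)


def flat_posterior_numeric(
    mu_c: float, var_c: float, var_r: float, reward: float
) -> tuple[float, float]:
    """Posterior mean/variance of the flat context given a reward, by quadrature."""
    grid = _grid([mu_c, reward], max(var_c, var_r))
    density = _normal_pdf(grid, mu_c, var_c) * _normal_pdf(reward, grid, var_r)
    return _moments(grid, density)


def cued_posterior_numeric(
    var_c: float, var_o: float, cue: float
) -> tuple[float, float]:
    """Posterior mean/variance of the cued context given its cue, by quadrature."""
    grid = _grid([0.0, cue], max(var_c, var_o))
    density = _normal_pdf(grid, 0.0, var_c) * _normal_pdf(cue, grid, var_o)
    return _moments(grid, density)


def cued_value_numeric(
    var_c: float, var_o: float, var_r: float, cue: float, reward: float
) -> float:
    """Incentive value under the cued model as a posterior-mean shift.

    The value is the shift of the context expectation produced by the
    reward: E[C | O, R] - E[C | O], both computed numerically.
    """
    grid = _grid([0.0, cue, reward], max(var_c, var_o, var_r))
    d_cue = _normal_pdf(grid, 0.0, var_c) * _normal_pdf(cue, grid, var_o)
    d_both = d_cue * _normal_pdf(reward, grid, var_r)
    return _moments(grid, d_both)[0] - _moments(grid, d_cue)[0]


def _hier_lc_density(
    var_hc: float,
    var_ho: float,
    var_lc: float,
    var_lo: float,
    high_cue: float,
    low_cue: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized density of LC given both cues, marginalized over HC."""
    max_var = max(var_hc, var_ho, var_lc, var_lo)
    hc = _grid([0.0, high_cue], max_var)
    lc = _grid([0.0, high_cue, low_cue], max_var)
    w_hc = _normal_pdf(hc, 0.0, var_hc) * _normal_pdf(high_cue, hc, var_ho)
    transfer = _normal_pdf(lc[:, None], hc[None, :], var_lc)
    marginal = np.trapezoid(transfer * w_hc[None, :], hc, axis=1)
    density = marginal * _normal_pdf(low_cue, lc, var_lo)
    return lc, density


def hierarchical_posterior_numeric(
    var_hc: float,
    var_ho: float,
    var_lc: float,
    var_lo: float,
    high_cue: float,
    low_cue: float,
) -> tuple[float, float]:
    """Posterior mean/variance of LC given both cues, by 2-D integration."""
    lc, density = _hier_lc_density(var_hc, var_ho, var_lc, var_lo, high_cue, low_cue)
    return _moments(lc, density)


def hierarchical_value_numeric(
    var_hc: float,
    var_ho: float,
    var_lc: float,
    var_lo: float,
    var_r: float,
    high_cue: float,
    low_cue: float,
    reward: float,
) -> float:
    """Incentive value under the hierarchical model as a posterior-mean shift.

    E[LC | HO, LO, R] - E[LC | HO, LO], both by numerical integration.
    """
    lc, d_cues = _hier_lc_density(var_hc, var_ho, var_lc, var_lo, high_cue, low_cue)
    d_all = d_cues * _normal_pdf(reward, lc, var_r)
    return _moments(lc, d_all)[0] - _moments(lc, d_cues)[0]
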