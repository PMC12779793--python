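"""Independent numeric oracle for Beta tail probabilities and quantiles.

Trapezoidal integration of the Beta density on a million-point grid, kept
deliberately independent of the special-function backend the library uses:
the only inputs are the shape parameters and elementary numpy operations.

The density is integrated after the substitution p = sin^2(theta), under
which a Beta(a, b) density becomes

    g(theta) = 2 sin(theta)^(2a-1) cos(theta)^(2b-1) / B(a, b)

on [0, pi/2].  For a, b >= 1/2 (every posterior under the Jeffreys prior)
g is bounded, so the endpoint singularities of the p-space density at x = 0
or x = n cost the trapezoid rule nothing.  The normalizing constant is
obtained numerically (total integral of g), not from a Beta-function call.
"""

from __future__ import annotations

import numpy as np

N_GRID = 1_000_001


def _theta_cdf(alpha: float, beta: float, npoints: int = N_GRID):
    theta = np.linspace(0.0, np.pi / 2.0, npoints)
    g = 2.0 * np.sin(theta) ** (2.0 * alpha - 1.0) * np.cos(theta) ** (2.0 * beta - 1.0)
    increments = 0.5 * (g[1:] + g[:-1]) * np.diff(theta)
    cdf = np.concatenate([[0.0], np.cumsum(increments)])
    cdf /= cdf[-1]  # numeric normalization; no Beta-function call
    return theta, cdf


def tail_prob(alpha: float, beta: float, p_star: float, npoints: int = N_GRID) -> float:
    """Pr(p >= p_star) for p ~ Beta(alpha, beta), by trapezoid quadrature."""
    theta, cdf = _theta_cdf(alpha, beta, npoints)
    t = np.arcsin(np.sqrt(p_star))
    return float(1.0 - np.interp(t, theta, cdf))


def quantile(alpha: float, beta: float, a: float, npoints: int = N_GRID) -> float:
    """The a-quantile of Beta(alpha, beta), by inverting the trapezoid CDF."""
    theta, cdf = _theta_cdf(alpha, beta, npoints)
    t = np.interp(a, cdf, theta)
    return float(np.sin(t) ** 2)
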