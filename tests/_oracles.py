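"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive: adaptive quadrature over the slab
density and root-finding on the quadrature posterior CDF.  These must stay
independent of the package's closed-form implementations.
"""

import math

import numpy as np
from scipy import integrate, optimize, stats


def slab_density(u, a):
    return (a / 2.0) * math.exp(-a * abs(u))


def marginal_quad(z, a):
    """(Laplace(a) * N(0,1))(z) by adaptive quadrature, split at 0 and z."""
    f = lambda u: slab_density(u, a) * stats.norm.pdf(z - u)
    pts = sorted({0.0, float(z)})
    lo, hi = min(pts) - 40.0, max(pts) + 40.0
    total = 0.0
    edges = [lo] + pts + [hi]
    for left, right in zip(edges[:-1], edges[1:]):
        val, _ = integrate.quad(f, left, right, limit=300)
        total += val
    return total


def posterior_nonzero_quad(z, w, a):
    g = marginal_quad(z, a)
    phi = stats.norm.pdf(z)
    return w * g / (w * g + (1.0 - w) * phi)


def posterior_median_quad(z, w, a):
    """Median of the posterior of the mean, by quadrature + root finding.

    Posterior: point mass (1-w) phi(z) at zero plus slab w gamma_a(u) phi(z-u),
    normalized.  Only z >= 0 is handled (use antisymmetry).
    """
    assert z >= 0.0
    if w == 0.0:
        return 0.0
    g = marginal_quad(z, a)
    norm = w * g + (1.0 - w) * stats.norm.pdf(z)

    def upper_mass(m):
        f = lambda u: slab_density(u, a) * stats.norm.pdf(z - u)
        pts = [p for p in (float(z),) if p > m]
        total = 0.0
        edges = [m] + pts + [max(m, z) + 40.0]
        for left, right in zip(edges[:-1], edges[1:]):
            val, _ = integrate.quad(f, left, right, limit=300)
            total += val
        return w * total / norm

    if upper_mass(0.0) <= 0.5:
        return 0.0
    return optimize.brentq(lambda m: upper_mass(m) - 0.5, 0.0, z + 20.0, xtol=1e-12)


def grid_search_max(fun, lo, hi, n=4001, refine=2):
    """Two-stage dense grid maximizer of a scalar function on [lo, hi]."""
    grid = np.linspace(lo, hi, n)
    vals = np.array([fun(x) for x in grid])
    best = int(np.argmax(vals))
    for _ in range(refine):
        left = grid[max(best - 1, 0)]
        right = grid[min(best + 1, len(grid) - 1)]
        grid = np.linspace(left, right, n)
        vals = np.array([fun(x) for x in grid])
        best = int(np.argmax(vals))
    return float(grid[best])
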