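"""Independent oracles used by the test suite.

These deliberately avoid the library's own vectorised/analytic code paths:
brute-force per-pixel loops for the rebinning, smooth fixed-order quadrature
for the orientation transform, and the classical series-inversion formula for
the Abel-type equation.  They are slow and simple on purpose.
"""

from __future__ import annotations

import math

import numpy as np

from saxsfibril.reduction import DetectorImage
from saxsfibril.geometry import QChiMap

TWO_PI = 2.0 * math.pi


def brute_force_radial_profile(
    image: DetectorImage, qmap: QChiMap, q_edges, sector=None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel python loop version of azimuthal_average (mean per q bin)."""
    nbins = len(q_edges) - 1
    sums = np.zeros(nbins)
    counts = np.zeros(nbins)
    nr, nc = image.counts.shape
    for i in range(nr):
        for j in range(nc):
            if not (image.mask[i, j] and qmap.valid[i, j]):
                continue
            chi = qmap.chi[i, j]
            if sector is not None:
                in_any = False
                for lo, hi in sector:
                    if ((chi - lo) % TWO_PI) <= ((hi - lo) % TWO_PI):
                        in_any = True
                        break
                if not in_any:
                    continue
            q = qmap.q_r[i, j]
            for b in range(nbins):
                if q_edges[b] <= q < q_edges[b + 1]:
                    sums[b] += image.counts[i, j]
                    counts[b] += 1
                    break
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def quadrature_forward(f_mu: np.ndarray, f_density: np.ndarray, chi_grid: np.ndarray,
                       n_quad: int = 4096) -> np.ndarray:
    """H(chi) by smooth high-order quadrature.

    With u = cos(mu) = cos(chi) * sin(theta) the transform becomes
    H = 4 * int_0^{pi/2} g(cos(chi) sin(theta)) dtheta, a smooth integrand,
    evaluated with Gauss-Legendre nodes.  ``g`` is the same piecewise-linear
    density model in u that the analytic operator assumes.
    """
    u_nodes = np.cos(f_mu)[::-1]  # increasing in u
    g_vals = f_density[::-1]
    # constant extension to u in [0, 1]
    theta, w = np.polynomial.legendre.leggauss(n_quad)
    theta = 0.5 * (theta + 1.0) * (math.pi / 2.0)
    w = w * (math.pi / 4.0)
    H = np.empty(len(chi_grid))
    for i, chi in enumerate(chi_grid):
        c = math.cos(chi)
        u = c * np.sin(theta)
        g = np.interp(u, u_nodes, g_vals, left=g_vals[0], right=g_vals[-1])
        H[i] = 4.0 * float(np.sum(w * g))
    return H


def schloemilch_inverse(chi_grid: np.ndarray, H: np.ndarray, mu_eval: np.ndarray,
                        n_quad: int = 512) -> np.ndarray:
    """Analytic inversion of the transform via the classical series formula.

    Writing F(c) = H(arccos c) / (2*pi), the equation takes the Schloemilch
    form F(c) = (2/pi) * int_0^{pi/2} g(c sin(theta)) dtheta with solution
    g(u) = F(0) + u * int_0^{pi/2} F'(u sin(theta)) dtheta.  Requires smooth
    noiseless H; derivatives are taken numerically on the c grid.
    """
    c_grid = np.cos(chi_grid)[::-1]
    F = (H / (2.0 * math.pi))[::-1]
    dF = np.gradient(F, c_grid)
    theta, w = np.polynomial.legendre.leggauss(n_quad)
    theta = 0.5 * (theta + 1.0) * (math.pi / 2.0)
    w = w * (math.pi / 4.0)
    F0 = float(np.interp(0.0, c_grid, F))
    out = np.empty(len(mu_eval))
    for i, mu in enumerate(mu_eval):
        u = math.cos(mu)
        dF_at = np.interp(u * np.sin(theta), c_grid, dF)
        out[i] = F0 + u * float(np.sum(w * dF_at))
    return out
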