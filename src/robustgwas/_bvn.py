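"""Closed-form bivariate normal probabilities via Owen's T function.

The selection-adjusted p-values of the two-phase tests reduce to one-dimensional
integrals whose integrand is a bivariate normal orthant probability.  Owen's T
gives that orthant probability in closed form to machine precision, fully
vectorised, which keeps the quadratures both deterministic and fast.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, owens_t

__all__ = ["bvn_cdf", "bvn_upper"]

_EPS = 1e-13


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal (X, Y) with correlation rho.

    Uses the Owen (1956) identity
    ``Phi2(h, k, rho) = (Phi(h) + Phi(k))/2 - T(h, a_h) - T(k, a_k) - beta``
    with ``beta = 1/2`` iff ``h * k < 0``.  Arguments broadcast.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    # Owen's identity is singular at h == 0 or k == 0; nudge by a sign-preserving
    # epsilon (error << 1e-13, below everything we ever resolve).
    h = np.where(h == 0.0, _EPS, h)
    k = np.where(k == 0.0, _EPS, k)
    rho = np.clip(rho, -1.0 + 1e-15, 1.0 - 1e-15)
    s = np.sqrt(1.0 - rho * rho)
    a_h = (k - rho * h) / (h * s)
    a_k = (h - rho * k) / (k * s)
    beta = np.where(h * k < 0.0, 0.5, 0.0)
    out = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, a_h) - owens_t(k, a_k) - beta
    return np.clip(out, 0.0, 1.0)


def bvn_upper(h, k, rho):
    """P(X > h, Y > k) for standard bivariate normal with correlation rho."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    return np.clip(1.0 - ndtr(h) - ndtr(k) + bvn_cdf(h, k, rho), 0.0, 1.0)
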