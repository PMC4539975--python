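"""Model-robust association tests and their selection-adjusted p-values.

Four robust tests for a single case-control genotype table, each built from
the trend tests ``Z_0, Z_1/2, Z_1`` (recessive / additive / dominant scores)
and, for the two-phase methods, the Hardy-Weinberg disequilibrium trend test
``Z_H``:

* MAX3  — ``max(|Z_0|, |Z_1/2|, |Z_1|)``; p-value by parametric bootstrap
  (or from the asymptotic trivariate normal of the three trend tests).
* MIN2  — ``min(P_chi2, P_1/2)``; the selection-adjusted p-value follows from
  the asymptotic decomposition of the Pearson statistic into the additive
  trend component plus an independent 1-df remainder.
* GMS   — genetic model selection: ``Z_H`` picks recessive (``Z_H > c``),
  dominant (``Z_H < -c``) or additive (otherwise) before testing, with the
  risk allele taken from the sign of ``Z_1/2``.
* GME   — genetic model exclusion: as GMS but testing with the standardised
  sums ``Z*_x = (Z_x + Z_1/2) / sqrt(2 (1 + rho_{x,1/2}))``.

GMS/GME p-values are the exact survival function of the oriented two-phase
statistic under the estimated null correlation structure, computed by
quadrature over closed-form bivariate normal orthant probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import integrate, stats
from scipy.special import ndtr

from ._bvn import bvn_cdf, bvn_upper
from .contingency import (
    CorrelationEstimates,
    DegenerateTableError,
    GenotypeCounts,
    _catt_z,
    _correlations,
    _pooled_freqs,
    catt,
    estimate_correlations,
    hwdtt,
    pearson_chi2,
)

__all__ = [
    "RobustTestResult",
    "max3_stat",
    "max3_pvalue",
    "min2_stat",
    "min2_pvalue",
    "gms_select",
    "gms_pvalue",
    "gme_stat",
    "gme_pvalue",
    "max3_test",
    "min2_test",
    "gms_test",
    "gme_test",
]

#: Truncation point for infinite normal limits (mass beyond < 1e-16).
_ZMAX = 8.5


@dataclass(frozen=True)
class RobustTestResult:
    """Outcome of a robust test: statistic, selection bookkeeping, p-value."""

    method: str
    statistic: float
    p_value: float | None = None
    selected_score: float | None = None  # CATT score x* in {0, 1/2, 1}
    component: str | None = None  # MIN2: "additive" or "chi2"
    direction: float | None = None  # sign carried to the replication stage
    zh_region: str | None = None  # GMS/GME: "above" | "within" | "below"
    z_h: float | None = None
    c: float | None = None
    alpha_h: float | None = None


def _phi(z):
    return np.exp(-0.5 * np.asarray(z) ** 2) / math.sqrt(2.0 * math.pi)


@lru_cache(maxsize=8)
def _leggauss(order: int):
    return np.polynomial.legendre.leggauss(order)


def _gl_map(lo, hi, order):
    """Gauss-Legendre nodes/weights mapped to [lo, hi]; lo/hi may be arrays."""
    u, w = _leggauss(order)
    lo = np.asarray(lo, dtype=float)[..., None]
    hi = np.asarray(hi, dtype=float)[..., None]
    half = 0.5 * (hi - lo)
    return lo + half * (u + 1.0), half * w


# ---------------------------------------------------------------------------
# MAX3
# ---------------------------------------------------------------------------

def max3_stat(counts: GenotypeCounts) -> RobustTestResult:
    """MAX3 statistic: the largest absolute trend test over the three models.

    Ties in the argmax are broken in recessive, additive, dominant order.
    """
    z = np.array([catt(counts, x).statistic for x in (0.0, 0.5, 1.0)])
    idx = int(np.argmax(np.abs(z)))
    score = (0.0, 0.5, 1.0)[idx]
    return RobustTestResult(
        method="MAX3",
        statistic=float(np.max(np.abs(z))),
        selected_score=score,
        direction=1.0 if z[idx] >= 0 else -1.0,
    )


def _max3_box(t, corr: CorrelationEstimates, order: int = 48) -> np.ndarray:
    """P(|Z_0| <= t, |Z_1/2| <= t, |Z_1| <= t) under the null correlations.

    One-dimensional quadrature conditioning on ``Z_1/2``; the conditional pair
    ``(Z_0, Z_1) | Z_1/2`` is bivariate normal with closed-form orthants.
    """
    t = np.asarray(t, dtype=float)
    r0a = np.asarray(corr.rho_0_half, dtype=float)
    r1a = np.asarray(corr.rho_1_half, dtype=float)
    r01 = np.asarray(corr.rho_0_1, dtype=float)
    s0 = np.sqrt(1.0 - r0a**2)
    s1 = np.sqrt(1.0 - r1a**2)
    rc = (r01 - r0a * r1a) / (s0 * s1)
    z, w = _gl_map(-t, t, order)
    t_, r0a_, r1a_, s0_, s1_, rc_ = (
        np.asarray(v)[..., None] for v in (t, r0a, r1a, s0, s1, rc)
    )
    h0, l0 = (t_ - r0a_ * z) / s0_, (-t_ - r0a_ * z) / s0_
    h1, l1 = (t_ - r1a_ * z) / s1_, (-t_ - r1a_ * z) / s1_
    box2 = (
        bvn_cdf(h0, h1, rc_)
        - bvn_cdf(l0, h1, rc_)
        - bvn_cdf(h0, l1, rc_)
        + bvn_cdf(l0, l1, rc_)
    )
    return np.clip((w * _phi(z) * box2).sum(axis=-1), 0.0, 1.0)


def max3_pvalue(
    counts: GenotypeCounts,
    b: int = 100_000,
    seed: int = 0,
    mode: str = "bootstrap",
) -> RobustTestResult:
    """MAX3 with its p-value.

    ``mode='bootstrap'`` (default): parametric bootstrap drawing case and
    control genotype vectors from multinomials at the pooled frequencies,
    p-value by the add-one estimator ``(1 + #{MAX3* >= observed}) / (b + 1)``.
    ``mode='asymptotic'``: survival probability of the trivariate normal of
    the three trend tests at the plug-in correlations (deterministic).
    """
    res = max3_stat(counts)
    if mode == "asymptotic":
        corr = estimate_correlations(counts)
        p = float(1.0 - _max3_box(res.statistic, corr))
        return replace(res, p_value=p)
    if mode != "bootstrap":
        raise ValueError(f"unknown mode {mode!r}")
    if b < 1000:
        raise ValueError("bootstrap needs b >= 1000")
    g = _pooled_freqs(counts.cases, counts.controls)
    rng = np.random.default_rng(seed)
    exceed = 0
    remaining = int(b)
    while remaining > 0:
        chunk = min(remaining, 200_000)
        cas = rng.multinomial(counts.r, g, size=chunk).astype(float)
        con = rng.multinomial(counts.s, g, size=chunk).astype(float)
        zs = np.stack([_catt_z(cas, con, x) for x in (0.0, 0.5, 1.0)])
        m = np.nanmax(np.abs(zs), axis=0)  # degenerate resamples carry no signal
        exceed += int(np.sum(m >= res.statistic))
        remaining -= chunk
    return replace(res, p_value=(1.0 + exceed) / (b + 1.0))


# ---------------------------------------------------------------------------
# MIN2
# ---------------------------------------------------------------------------

def min2_stat(counts: GenotypeCounts) -> RobustTestResult:
    """MIN2 statistic: the smaller of the Pearson and additive-trend p-values."""
    p_chi2 = pearson_chi2(counts).p_value
    add = catt(counts, 0.5)
    if add.p_value <= p_chi2:  # tie goes to the additive component
        comp, m = "additive", add.p_value
    else:
        comp, m = "chi2", p_chi2
    return RobustTestResult(
        method="MIN2",
        statistic=float(m),
        component=comp,
        selected_score=0.5 if comp == "additive" else None,
        direction=1.0 if add.statistic >= 0 else -1.0,
    )


def _s1(w):
    """Survival function of chi-square with 1 df, vectorised."""
    return 2.0 * ndtr(-np.sqrt(np.clip(w, 0.0, None)))


def _h1(v):
    """Density of chi-square with 1 df."""
    v = np.asarray(v, dtype=float)
    return np.exp(-0.5 * v) / np.sqrt(2.0 * math.pi * v)


def min2_pvalue(min2: float) -> float:
    """Selection-adjusted p-value of MIN2.

    Under the null the Pearson statistic decomposes as ``T = Z_1/2^2 + W``
    with ``W`` an independent 1-df chi-square; with ``a = H_1^{-1}(1 - m)``
    and ``b = -2 log m`` (the 2-df quantile),

        P(MIN2 <= m) = 2 m - S_1(b) - int_a^b h_1(v) S_1(b - v) dv,

    which always lies in ``[m, 2 m]``.
    """
    m = float(min2)
    if not 0.0 < m <= 1.0:
        raise ValueError(f"MIN2 statistic must be in (0, 1], got {m}")
    if m == 1.0:
        return 1.0
    a = float(stats.chi2.isf(m, 1))
    b = -2.0 * math.log(m)
    integral, _ = integrate.quad(
        lambda v: _h1(v) * _s1(b - v), a, b, epsabs=1e-10, limit=200
    )
    return float(np.clip(2.0 * m - _s1(b) - integral, 0.0, 1.0))


def _min2_pvalue_batch(m: np.ndarray, order: int = 64) -> np.ndarray:
    """Vectorised Eq-for-MIN2 adjustment on an array of minima in (0, 1)."""
    m = np.asarray(m, dtype=float)
    a = stats.chi2.isf(m, 1)
    b = -2.0 * np.log(m)
    v, w = _gl_map(a, b, order)
    integral = (w * _h1(v) * _s1(b[..., None] - v)).sum(axis=-1)
    return np.clip(2.0 * m - _s1(b) - integral, 0.0, 1.0)


# ---------------------------------------------------------------------------
# GMS / GME
# ---------------------------------------------------------------------------

def _zh_region(z_h: float, c: float) -> str:
    if z_h > c:
        return "above"
    if z_h < -c:
        return "below"
    return "within"


def gms_select(counts: GenotypeCounts, alpha_h: float = 0.05) -> RobustTestResult:
    """Genetic model selection statistic.

    With ``c = Phi^{-1}(1 - alpha_h)`` and risk allele B (``Z_1/2 > 0``):
    ``Z_GMS = Z_0`` if ``Z_H > c`` (recessive), ``Z_1`` if ``Z_H < -c``
    (dominant), ``Z_1/2`` otherwise.  When ``Z_1/2 <= 0`` (risk allele A) the
    recessive/dominant roles exchange and the statistics are negated:
    ``-Z_1``, ``-Z_1/2``, ``-Z_0`` respectively.
    """
    c = float(stats.norm.isf(alpha_h))
    z = {x: catt(counts, x).statistic for x in (0.0, 0.5, 1.0)}
    z_h = hwdtt(counts).z_h
    region = _zh_region(z_h, c)
    if z[0.5] > 0:
        score = {"above": 0.0, "within": 0.5, "below": 1.0}[region]
        statistic = z[score]
        direction = 1.0
    else:
        score = {"above": 1.0, "within": 0.5, "below": 0.0}[region]
        statistic = -z[score]
        direction = -1.0
    return RobustTestResult(
        method="GMS",
        statistic=float(statistic),
        selected_score=score,
        direction=direction,
        zh_region=region,
        z_h=float(z_h),
        c=c,
        alpha_h=float(alpha_h),
    )


def _starred_corr(r_xh, r_xa, rhh):
    """Correlations of Z*_x = (Z_x + Z_1/2)/sqrt(2(1+rho_x,1/2)) with Z_H, Z_1/2."""
    denom = np.sqrt(2.0 * (1.0 + r_xa))
    return (r_xh + rhh) / denom, (1.0 + r_xa) / denom


def _selection_survival_batch(
    t, corr: CorrelationEstimates, c: float, starred: bool, order: int = 48
) -> np.ndarray:
    """P(oriented two-phase statistic > t) under the null; vectorised over tables.

    Sum of the recessive and dominant selection terms (trivariate normal
    orthant probabilities, reduced to 1-d quadrature over ``Z_H`` with
    closed-form conditional bivariate orthants) plus the additive term; the
    leading factor 2 accounts for the two equiprobable risk-allele branches.
    """
    t = np.asarray(t, dtype=float)
    rhh = np.asarray(corr.rho_half, dtype=float)
    total = np.zeros(np.broadcast(t, rhh).shape)
    for x, lo, hi in ((0.0, c, _ZMAX), (1.0, -_ZMAX, -c)):
        r_xh = np.asarray(corr.rho_0 if x == 0.0 else corr.rho_1, dtype=float)
        r_xa = np.asarray(corr.rho_0_half if x == 0.0 else corr.rho_1_half, dtype=float)
        if starred:
            r_xh, r_xa = _starred_corr(r_xh, r_xa, rhh)
        sx = np.sqrt(1.0 - r_xh**2)
        sa = np.sqrt(1.0 - rhh**2)
        rc = (r_xa - r_xh * rhh) / (sx * sa)
        # the four statistics span a rank-2 Gaussian space, so the conditional
        # pair is (near-)perfectly correlated and the integrand has a kink
        # where the two conditional thresholds cross; split the panel there
        denom = r_xh * sa - rhh * sx
        with np.errstate(divide="ignore", invalid="ignore"):
            kink = np.where(np.abs(denom) > 1e-12, t * sa / denom, np.inf)
        lo_b = np.broadcast_to(lo, np.broadcast(t, rhh).shape)
        hi_b = np.broadcast_to(hi, np.broadcast(t, rhh).shape)
        mid = np.clip(kink, lo_b, hi_b)
        term = np.zeros(np.broadcast(t, rhh).shape)
        for a, b in ((lo_b, mid), (mid, hi_b)):
            z, w = _gl_map(a, b, order)
            orthant = bvn_upper(
                (t[..., None] - r_xh[..., None] * z) / sx[..., None],
                (-rhh[..., None] * z) / sa[..., None],
                rc[..., None],
            )
            term = term + (w * _phi(z) * orthant).sum(axis=-1)
        total = total + 2.0 * term
    # additive branch: |Z_H| <= c and Z_1/2 beyond max(t, 0)
    sa = np.sqrt(1.0 - rhh**2)
    z, w = _gl_map(np.broadcast_to(-c, t.shape), np.broadcast_to(c, t.shape), order)
    tail = ndtr((rhh[..., None] * z - np.maximum(t, 0.0)[..., None]) / sa[..., None])
    total = total + 2.0 * (w * _phi(z) * tail).sum(axis=-1)
    return np.clip(total, 0.0, 1.0)


def _selection_survival_quad(
    t: float, corr: CorrelationEstimates, c: float, starred: bool
) -> float:
    """Adaptive-quadrature evaluation of the same survival function (scalar)."""
    rhh = corr.rho_half
    total = 0.0
    for x, lo, hi in ((0.0, c, _ZMAX), (1.0, -_ZMAX, -c)):
        r_xh = corr.rho_0 if x == 0.0 else corr.rho_1
        r_xa = corr.rho_0_half if x == 0.0 else corr.rho_1_half
        if starred:
            r_xh, r_xa = (float(v) for v in _starred_corr(r_xh, r_xa, rhh))
        sx = math.sqrt(1.0 - r_xh**2)
        sa = math.sqrt(1.0 - rhh**2)
        rc = (r_xa - r_xh * rhh) / (sx * sa)

        def integrand(z, r_xh=r_xh, sx=sx, sa=sa, rc=rc):
            return float(
                _phi(z) * bvn_upper((t - r_xh * z) / sx, (-rhh * z) / sa, rc)
            )

        val, _ = integrate.quad(integrand, lo, hi, epsabs=1e-9, limit=200)
        total += 2.0 * val
    sa = math.sqrt(1.0 - rhh**2)
    tmax = max(t, 0.0)
    val, _ = integrate.quad(
        lambda z: float(_phi(z) * ndtr((rhh * z - tmax) / sa)), -c, c,
        epsabs=1e-9, limit=200,
    )
    return float(np.clip(total + 2.0 * val, 0.0, 1.0))


def _as_stat(result_or_t, default_c: float | None) -> tuple[float, float]:
    if isinstance(result_or_t, RobustTestResult):
        c = result_or_t.c if result_or_t.c is not None else default_c
        return float(result_or_t.statistic), float(c)
    if default_c is None:
        raise ValueError("alpha_h is required when a bare statistic is given")
    return float(result_or_t), float(default_c)


def gms_pvalue(
    gms, corr: CorrelationEstimates, alpha_h: float | None = 0.05
) -> float:
    """Selection-adjusted p-value of the GMS statistic.

    ``gms`` may be the result of :func:`gms_select` (its stored threshold is
    used) or a bare statistic value.  The p-value is the survival function of
    the oriented GMS statistic under the plug-in null correlations, strictly
    decreasing in the statistic.
    """
    _check_corr(corr)
    c = None if alpha_h is None else float(stats.norm.isf(alpha_h))
    t, c = _as_stat(gms, c)
    return _selection_survival_quad(t, corr, c, starred=False)


def gme_stat(counts: GenotypeCounts, alpha_h: float = 0.05) -> RobustTestResult:
    """Genetic model exclusion statistic.

    Same selection regions as GMS, but the extreme-model trend tests are
    replaced by the unit-variance sums ``Z*_x = (Z_x + Z_1/2) /
    sqrt(2 (1 + rho_x,1/2))`` (``Z*_1/2 = Z_1/2``), which hedge against the
    unlikely model instead of committing to it.
    """
    c = float(stats.norm.isf(alpha_h))
    z = {x: catt(counts, x).statistic for x in (0.0, 0.5, 1.0)}
    corr = estimate_correlations(counts)
    z_star = {
        0.0: (z[0.0] + z[0.5]) / math.sqrt(2.0 * (1.0 + corr.rho_0_half)),
        0.5: z[0.5],
        1.0: (z[1.0] + z[0.5]) / math.sqrt(2.0 * (1.0 + corr.rho_1_half)),
    }
    z_h = hwdtt(counts).z_h
    region = _zh_region(z_h, c)
    if z[0.5] > 0:
        score = {"above": 0.0, "within": 0.5, "below": 1.0}[region]
        statistic = z_star[score]
        direction = 1.0
    else:
        score = {"above": 1.0, "within": 0.5, "below": 0.0}[region]
        statistic = -z_star[score]
        direction = -1.0
    return RobustTestResult(
        method="GME",
        statistic=float(statistic),
        selected_score=score,
        direction=direction,
        zh_region=region,
        z_h=float(z_h),
        c=c,
        alpha_h=float(alpha_h),
    )


def gme_pvalue(
    gme, corr: CorrelationEstimates, alpha_h: float | None = 0.05
) -> float:
    """Selection-adjusted p-value of the GME statistic (see :func:`gms_pvalue`)."""
    _check_corr(corr)
    c = None if alpha_h is None else float(stats.norm.isf(alpha_h))
    t, c = _as_stat(gme, c)
    return _selection_survival_quad(t, corr, c, starred=True)


def _check_corr(corr: CorrelationEstimates) -> None:
    m = corr.matrix()
    if np.ndim(m) == 2 and np.min(np.linalg.eigvalsh(m)) < -1e-10:
        raise ValueError("correlation matrix is not positive semi-definite")


# ---------------------------------------------------------------------------
# convenience wrappers: statistic + p-value in one call
# ---------------------------------------------------------------------------

def max3_test(counts: GenotypeCounts, b: int = 100_000, seed: int = 0,
              mode: str = "bootstrap") -> RobustTestResult:
    return max3_pvalue(counts, b=b, seed=seed, mode=mode)


def min2_test(counts: GenotypeCounts) -> RobustTestResult:
    res = min2_stat(counts)
    return replace(res, p_value=min2_pvalue(res.statistic))


def gms_test(counts: GenotypeCounts, alpha_h: float = 0.05) -> RobustTestResult:
    res = gms_select(counts, alpha_h)
    p = gms_pvalue(res, estimate_correlations(counts))
    return replace(res, p_value=p)


def gme_test(counts: GenotypeCounts, alpha_h: float = 0.05) -> RobustTestResult:
    res = gme_stat(counts, alpha_h)
    p = gme_pvalue(res, estimate_correlations(counts))
    return replace(res, p_value=p)
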