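"""Single-table association statistics for case-control 2x3 genotype tables.

For a biallelic marker with alleles A and B, the genotype counts of ``r`` cases
and ``s`` controls form a 2x3 table::

                AA (G0)   AB (G1)   BB (G2)
    cases         r0        r1        r2
    controls      s0        s1        s2

This module provides the classical tests on a single table — the Cochran-
Armitage trend test (CATT) with scores ``(0, x, 1)``, Pearson's 2-df chi-square
test, the allele-based test (ABT), and the Hardy-Weinberg disequilibrium trend
test (HWDTT) — together with plug-in estimates of the null correlations among
the trend tests and the HWDTT that the two-phase robust tests require.

All z statistics are signed so that a positive value means allele B is
over-represented in cases (for the HWDTT: excess homozygosity in cases).
Two-sided p-values follow the ``2 * (1 - Phi(|z|))`` convention, and
``sign(0)`` is taken as ``+1`` wherever a direction is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy import stats
from scipy.special import ndtr

__all__ = [
    "DegenerateTableError",
    "GenotypeCounts",
    "GeneticModel",
    "MODEL_SCORES",
    "TestResult",
    "HwdttResult",
    "CorrelationEstimates",
    "catt",
    "pearson_chi2",
    "abt",
    "hwdtt",
    "estimate_correlations",
]


class DegenerateTableError(ValueError):
    """The test statistic is undefined for this table (zero score variance)."""


#: Optimal CATT score for each genetic model label.
MODEL_SCORES = {"REC": 0.0, "ADD": 0.5, "MUL": 0.5, "DOM": 1.0}


@dataclass(frozen=True)
class GeneticModel:
    """A genetic model label and its optimal CATT score."""

    label: str

    def __post_init__(self) -> None:
        if self.label not in MODEL_SCORES:
            raise ValueError(f"unknown genetic model {self.label!r}")

    @property
    def score(self) -> float:
        return MODEL_SCORES[self.label]


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts of one marker: (r0, r1, r2) cases, (s0, s1, s2) controls."""

    r0: int
    r1: int
    r2: int
    s0: int
    s1: int
    s2: int

    def __post_init__(self) -> None:
        for name in ("r0", "r1", "r2", "s0", "s1", "s2"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"count {name} must be a non-negative integer, got {v!r}")

    @property
    def cases(self) -> np.ndarray:
        return np.array([self.r0, self.r1, self.r2], dtype=float)

    @property
    def controls(self) -> np.ndarray:
        return np.array([self.s0, self.s1, self.s2], dtype=float)

    @property
    def r(self) -> int:
        return self.r0 + self.r1 + self.r2

    @property
    def s(self) -> int:
        return self.s0 + self.s1 + self.s2

    @property
    def n(self) -> int:
        return self.r + self.s

    @property
    def n_i(self) -> np.ndarray:
        return self.cases + self.controls

    @property
    def is_degenerate(self) -> bool:
        """True when every observation carries a single genotype."""
        return bool(np.max(self.n_i) == self.n)

    def swapped(self) -> "GenotypeCounts":
        """Cases and controls exchanged."""
        return GenotypeCounts(self.s0, self.s1, self.s2, self.r0, self.r1, self.r2)

    def relabelled(self) -> "GenotypeCounts":
        """Alleles A and B exchanged (genotype order reversed)."""
        return GenotypeCounts(self.r2, self.r1, self.r0, self.s2, self.s1, self.s0)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    label: str
    df: float | None = None
    score: float | None = None


@dataclass(frozen=True)
class HwdttResult:
    z_h: float
    delta_p_hat: float
    delta_q_hat: float
    p_value: float


@dataclass(frozen=True)
class CorrelationEstimates:
    """Plug-in null correlations among (Z_0, Z_1/2, Z_1, Z_H).

    ``rho_0_half``, ``rho_1_half`` and ``rho_0_1`` are the trend-test pair
    correlations; ``rho_0``, ``rho_1`` and ``rho_half`` are the correlations of
    the respective trend test with the HWDTT.
    """

    rho_0_half: float
    rho_1_half: float
    rho_0_1: float
    rho_0: float
    rho_1: float
    rho_half: float

    def matrix(self) -> np.ndarray:
        """4x4 correlation matrix in the order (Z_0, Z_1/2, Z_1, Z_H)."""
        r = np.asarray(
            [
                [1.0, self.rho_0_half, self.rho_0_1, self.rho_0],
                [self.rho_0_half, 1.0, self.rho_1_half, self.rho_half],
                [self.rho_0_1, self.rho_1_half, 1.0, self.rho_1],
                [self.rho_0, self.rho_half, self.rho_1, 1.0],
            ]
        )
        # batch input (array fields): move the 4x4 axes last
        return np.moveaxis(r, (0, 1), (-2, -1)) if r.ndim > 2 else r


def _two_sided(z) -> np.ndarray:
    return 2.0 * (1.0 - ndtr(np.abs(z)))


# ---------------------------------------------------------------------------
# vectorised kernels; ``cases``/``controls`` are float arrays of shape (..., 3)
# ---------------------------------------------------------------------------

def _catt_z(cases: np.ndarray, controls: np.ndarray, x: float) -> np.ndarray:
    r = cases.sum(axis=-1)
    s = controls.sum(axis=-1)
    n = r + s
    n_i = cases + controls
    xs = np.array([0.0, float(x), 1.0])
    num = (xs * (s[..., None] * cases - r[..., None] * controls)).sum(axis=-1)
    a = (xs * xs * n_i).sum(axis=-1)
    b = (xs * n_i).sum(axis=-1)
    den2 = r * s * (n * a - b * b)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(n) * num / np.sqrt(den2)


def _pearson_t(cases: np.ndarray, controls: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Pearson statistic and df; empty genotype columns are dropped from df."""
    r = cases.sum(axis=-1, keepdims=True)
    s = controls.sum(axis=-1, keepdims=True)
    n_i = cases + controls
    n = r + s
    e_case = n_i * r / n
    e_ctrl = n_i * s / n
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(n_i > 0, (cases - e_case) ** 2 / e_case, 0.0).sum(axis=-1)
        t = t + np.where(n_i > 0, (controls - e_ctrl) ** 2 / e_ctrl, 0.0).sum(axis=-1)
    df = (n_i > 0).sum(axis=-1) - 1
    return t, df


def _abt_z(cases: np.ndarray, controls: np.ndarray) -> np.ndarray:
    r = cases.sum(axis=-1)
    s = controls.sum(axis=-1)
    n = r + s
    n_i = cases + controls
    a = 2.0 * cases[..., 2] + cases[..., 1]  # B alleles in cases
    b = 2.0 * controls[..., 2] + controls[..., 1]
    theta = (2.0 * n_i[..., 2] + n_i[..., 1]) / (2.0 * n)
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = a / (2.0 * r) - b / (2.0 * s)
        var = theta * (1.0 - theta) * (1.0 / (2.0 * r) + 1.0 / (2.0 * s))
        return diff / np.sqrt(var)


def _hwd_deltas(cases: np.ndarray, controls: np.ndarray):
    r = cases.sum(axis=-1)
    s = controls.sum(axis=-1)
    p_hat = cases / r[..., None]
    q_hat = controls / s[..., None]
    d_p = p_hat[..., 2] - (p_hat[..., 2] + p_hat[..., 1] / 2.0) ** 2
    d_q = q_hat[..., 2] - (q_hat[..., 2] + q_hat[..., 1] / 2.0) ** 2
    return d_p, d_q


def _hwdtt_z(cases: np.ndarray, controls: np.ndarray) -> np.ndarray:
    r = cases.sum(axis=-1)
    s = controls.sum(axis=-1)
    n = r + s
    n_i = cases + controls
    d_p, d_q = _hwd_deltas(cases, controls)
    theta = (n_i[..., 2] + n_i[..., 1] / 2.0) / n  # pooled B-allele frequency
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(r * s / n) * (d_p - d_q) / (theta * (1.0 - theta))


def _pooled_freqs(cases: np.ndarray, controls: np.ndarray) -> np.ndarray:
    n_i = cases + controls
    return n_i / n_i.sum(axis=-1, keepdims=True)


def _corr_linear(g: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Null correlation of two case-minus-control linear genotype functionals.

    Under H0 both groups draw from the same multinomial ``g``; the difference
    structure cancels, leaving ``Corr = Cov_g(u, v)/sqrt(Var_g(u) Var_g(v))``.
    """
    mu_u = (u * g).sum(axis=-1)
    mu_v = (v * g).sum(axis=-1)
    cov = (u * v * g).sum(axis=-1) - mu_u * mu_v
    var_u = (u * u * g).sum(axis=-1) - mu_u**2
    var_v = (v * v * g).sum(axis=-1) - mu_v**2
    with np.errstate(divide="ignore", invalid="ignore"):
        return cov / np.sqrt(var_u * var_v)


def _correlations(cases: np.ndarray, controls: np.ndarray) -> CorrelationEstimates:
    """Plug-in correlations; vectorised (fields become arrays for batch input)."""
    g = _pooled_freqs(cases, controls)
    theta = g[..., 2] + g[..., 1] / 2.0
    zeros = np.zeros_like(theta)
    ones = np.ones_like(theta)
    s0 = np.stack([zeros, zeros, ones], axis=-1)
    sh = np.stack([zeros, 0.5 * ones, ones], axis=-1)
    s1 = np.stack([zeros, ones, ones], axis=-1)
    # delta-method influence vector of the HWD coefficient at the pooled freqs
    h = np.stack([zeros, -theta, 1.0 - 2.0 * theta], axis=-1)
    return CorrelationEstimates(
        rho_0_half=_corr_linear(g, s0, sh),
        rho_1_half=_corr_linear(g, s1, sh),
        rho_0_1=_corr_linear(g, s0, s1),
        rho_0=_corr_linear(g, s0, h),
        rho_1=_corr_linear(g, s1, h),
        rho_half=_corr_linear(g, sh, h),
    )


# ---------------------------------------------------------------------------
# public single-table API
# ---------------------------------------------------------------------------

def _require_valid(counts: GenotypeCounts) -> None:
    if counts.r == 0 or counts.s == 0:
        raise DegenerateTableError("both cases and controls must be observed")
    if counts.is_degenerate:
        raise DegenerateTableError("all observations carry a single genotype")


def catt(counts: GenotypeCounts, x: float = 0.5) -> TestResult:
    """Cochran-Armitage trend test with genotype scores ``(0, x, 1)``.

    ``x`` encodes the genetic model: 0 recessive, 1/2 additive/multiplicative,
    1 dominant.  Positive statistic: allele B over-represented in cases.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"score x must be in [0, 1], got {x}")
    _require_valid(counts)
    n_i = counts.n_i
    xs = np.array([0.0, x, 1.0])
    if counts.n * (xs**2 * n_i).sum() - (xs * n_i).sum() ** 2 <= 0:
        raise DegenerateTableError("trend score has zero variance on this table")
    z = float(_catt_z(counts.cases, counts.controls, x))
    return TestResult(statistic=z, p_value=float(_two_sided(z)), label="CATT", score=x)


def pearson_chi2(counts: GenotypeCounts) -> TestResult:
    """Pearson's chi-square test of general genotype association (2 df).

    Genotype classes absent from the pooled sample are dropped and the degrees
    of freedom reduced accordingly.
    """
    _require_valid(counts)
    t, df = _pearson_t(counts.cases, counts.controls)
    t, df = float(t), int(df)
    return TestResult(statistic=t, p_value=float(stats.chi2.sf(t, df)), label="CHI2", df=df)


def abt(counts: GenotypeCounts) -> TestResult:
    """Allele-based test comparing B-allele frequencies in cases vs controls.

    Valid as a standard normal only under Hardy-Weinberg equilibrium.
    """
    _require_valid(counts)
    n_i = counts.n_i
    if (2 * n_i[0] + n_i[1]) <= 0 or (n_i[1] + 2 * n_i[2]) <= 0:
        raise DegenerateTableError("only one allele observed")
    z = float(_abt_z(counts.cases, counts.controls))
    return TestResult(statistic=z, p_value=float(_two_sided(z)), label="ABT")


def hwdtt(counts: GenotypeCounts) -> HwdttResult:
    """Hardy-Weinberg disequilibrium trend test.

    Compares the HWD coefficient estimates ``Delta = Pr(BB) - theta_B^2``
    between cases and controls; its sign separates recessive (positive) from
    dominant (negative) risk-allele models.
    """
    if counts.r == 0 or counts.s == 0:
        raise DegenerateTableError("both cases and controls must be observed")
    n_i = counts.n_i
    theta = (n_i[2] + n_i[1] / 2.0) / counts.n
    if theta <= 0.0 or theta >= 1.0:
        raise DegenerateTableError("only one allele observed")
    d_p, d_q = _hwd_deltas(counts.cases, counts.controls)
    z = float(_hwdtt_z(counts.cases, counts.controls))
    return HwdttResult(
        z_h=z, delta_p_hat=float(d_p), delta_q_hat=float(d_q), p_value=float(_two_sided(z))
    )


def estimate_correlations(counts: GenotypeCounts) -> CorrelationEstimates:
    """Plug-in estimates of the null correlations among (Z_0, Z_1/2, Z_1, Z_H).

    Trend-test pairs use the closed-form multinomial covariance of the score
    functionals at the pooled genotype frequencies ``n_i / n``; trend-vs-HWDTT
    correlations linearise the HWD coefficient (delta method) at the same
    frequencies.  The implied 4x4 matrix is a genuine correlation matrix of
    linear functionals of one multinomial, hence positive semi-definite.
    """
    _require_valid(counts)
    g = _pooled_freqs(counts.cases, counts.controls)
    if g[0] <= 0.0 or g[2] <= 0.0:
        raise DegenerateTableError(
            "pooled frequency of a homozygote genotype is zero; correlations undefined"
        )
    est = _correlations(counts.cases, counts.controls)
    return CorrelationEstimates(*(float(getattr(est, f)) for f in (
        "rho_0_half", "rho_1_half", "rho_0_1", "rho_0", "rho_1", "rho_half")))
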