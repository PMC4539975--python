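"""Joint discovery + replication evidence conditional on stage-1 selection.

Only markers with discovery p-value below the stage-1 level ``alpha_D`` enter
replication, so the joint p-value of a combination statistic must condition
on that selection:  ``p = P_H0(P1 < alpha_D, statistic > observed)``.

Two combinations are provided.

Fisher (FC): ``Z_FC = -2 w1 ln P1 - 2 w2 ln P2`` with closed-form conditional
p-value — for equal weights ``e^{-z/2} (1 + z/2 + ln alpha_D)`` on the support
``z > -2 ln alpha_D`` (natural logarithms throughout), and a two-exponential
form for unequal weights.

Inverse-normal linear combination (LC):
``Z_LC = (w1 Phi^{-1}(1 - P1/2) + w2 Phi^{-1}(1 - P2)) / sqrt(w1^2 + w2^2)``
— the discovery p-value is two-sided (hence halved), the replication p-value
one-sided.  Its conditional p-value is a one-dimensional normal integral on
the support ``z_LC > z_{1 - alpha_D/2}``.

The LC integral is published with the standard-normal density for the
discovery probit, whose null distribution is actually half-normal; the
resulting value is exactly half the conditional probability
``P(P1 < alpha_D, Z_LC > z)``.  ``lc_pvalue`` evaluates the published form by
default and the exact conditional probability with ``exact=True`` (the form
the type-I-error simulations calibrate against).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import integrate, optimize, stats
from scipy.special import ndtr, ndtri

__all__ = [
    "CombinedConfig",
    "CombinedResult",
    "fisher_stat",
    "fisher_pvalue",
    "lc_stat",
    "lc_pvalue",
    "fc_threshold",
    "lc_threshold",
]

#: weight pairs below this separation use the equal-weight closed form
_EQUAL_TOL = 1e-9


@dataclass(frozen=True)
class CombinedConfig:
    """Stage-1 level, weighting scheme and combination choice.

    With ``weight_scheme='sample_size'`` the weights follow the stage split
    ``pi_s`` (discovery fraction of the total sample): ``(2 pi_s, 2 (1-pi_s))``
    for FC and ``(sqrt(pi_s), sqrt(1-pi_s))`` for LC.
    """

    alpha_d: float
    weight_scheme: str = "equal"
    pi_s: float | None = None
    combination: str = "FC"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_d <= 1.0:
            raise ValueError(f"alpha_d must be in (0, 1], got {self.alpha_d}")
        if self.weight_scheme not in ("equal", "sample_size"):
            raise ValueError(f"unknown weight scheme {self.weight_scheme!r}")
        if self.combination not in ("FC", "LC"):
            raise ValueError(f"unknown combination {self.combination!r}")
        if self.weight_scheme == "sample_size":
            if self.pi_s is None or not 0.0 < self.pi_s < 1.0:
                raise ValueError("sample_size weights need pi_s in (0, 1)")

    def weights(self) -> tuple[float, float]:
        if self.weight_scheme == "equal":
            return 1.0, 1.0
        if self.combination == "FC":
            return 2.0 * self.pi_s, 2.0 * (1.0 - self.pi_s)
        return math.sqrt(self.pi_s), math.sqrt(1.0 - self.pi_s)


@dataclass(frozen=True)
class CombinedResult:
    statistic: float
    p_value: float
    combination: str
    weights: tuple[float, float]
    alpha_d: float
    valid: bool = True


def fisher_stat(p1: float, p2: float, w1: float = 1.0, w2: float = 1.0) -> float:
    """``Z_FC = -2 w1 ln(p1) - 2 w2 ln(p2)`` (natural logarithm)."""
    if not (0.0 < p1 <= 1.0 and 0.0 < p2 <= 1.0):
        raise ValueError("p-values must be in (0, 1]")
    return -2.0 * w1 * math.log(p1) - 2.0 * w2 * math.log(p2)


def fisher_pvalue(z_fc: float, config: CombinedConfig) -> CombinedResult:
    """Conditional p-value ``P_H0(P1 < alpha_D, Z_FC > z_fc)``.

    Closed forms; below the support threshold (``-2 w1 ln alpha_D``) the event
    ``P1 < alpha_D`` alone forces a larger statistic, so the marker could not
    have produced this value after stage-1 selection.
    """
    w1, w2 = config.weights()
    if w1 <= 0 or w2 <= 0:
        raise ValueError("weights must be positive")
    la = math.log(config.alpha_d)
    if z_fc < -2.0 * w1 * la:  # boundary itself is attainable (p = alpha_d there)
        raise ValueError(
            f"z_fc={z_fc:.6g} is below the support threshold {-2.0 * w1 * la:.6g}: "
            f"a marker selected at alpha_d={config.alpha_d:g} cannot yield it"
        )
    if abs(w1 - w2) < _EQUAL_TOL:
        z = z_fc / w1  # rescale to unit weights
        p = math.exp(-z / 2.0) * (1.0 + z / 2.0 + la)
    else:
        p = (w1 / (w1 - w2)) * math.exp(-z_fc / (2.0 * w1)) - (
            w2 / (w1 - w2)
        ) * math.exp(-z_fc / (2.0 * w2)) * config.alpha_d ** (-(w1 - w2) / w2)
    p = min(max(p, 0.0), config.alpha_d)
    return CombinedResult(z_fc, p, "FC", (w1, w2), config.alpha_d)


def lc_stat(p1: float, p2: float, config: CombinedConfig) -> float:
    """Inverse-normal combination; discovery two-sided p halved, replication not."""
    if not 0.0 < p1 <= 1.0:
        raise ValueError("p1 must be in (0, 1]")
    if not 0.0 < p2 < 1.0:
        raise ValueError("p2 must be in (0, 1)")
    w1, w2 = config.weights()
    return float(
        (w1 * ndtri(1.0 - p1 / 2.0) + w2 * ndtri(1.0 - p2))
        / math.sqrt(w1 * w1 + w2 * w2)
    )


def _phi(z: float) -> float:
    return math.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)


def _lc_integral(z_lc: float, w1: float, w2: float, alpha_d: float) -> float:
    """The conditional-probability integral of the LC statistic (no support
    restriction; monotone decreasing in ``z_lc`` with limit ``alpha_d/2``)."""
    q = float(ndtri(1.0 - alpha_d / 2.0))
    norm = math.sqrt(w1 * w1 + w2 * w2)
    upper = max(q, norm * z_lc / w1) + 8.5 * w2 / w1 + 1.0

    def integrand(z: float) -> float:
        return _phi(z) * (1.0 - ndtr((norm * z_lc - w1 * z) / w2))

    val, _ = integrate.quad(integrand, q, upper, epsabs=1e-12, limit=200)
    return val + 1.0 - ndtr(upper)  # tail where the bracket is ~1


def lc_pvalue(z_lc: float, config: CombinedConfig, exact: bool = False) -> CombinedResult:
    """Conditional p-value of the inverse-normal combination.

    Evaluates ``int_{z_{1-alpha_D/2}}^inf phi(z) [1 - Phi((sqrt(w1^2+w2^2)
    z_lc - w1 z)/w2)] dz`` (published form, ceiling ``alpha_D/2``); with
    ``exact=True`` returns twice that — the half-normal discovery probit makes
    this the true conditional probability ``P(P1 < alpha_D, Z_LC > z_lc)``.
    """
    w1, w2 = config.weights()
    q = float(ndtri(1.0 - config.alpha_d / 2.0))
    if z_lc <= q:
        raise ValueError(
            f"z_lc={z_lc:.6g} is below the support threshold {q:.6g} "
            f"for alpha_d={config.alpha_d:g}"
        )
    val = _lc_integral(z_lc, w1, w2, config.alpha_d)
    if exact:
        val *= 2.0
    cap = config.alpha_d if exact else config.alpha_d / 2.0
    return CombinedResult(z_lc, min(max(val, 0.0), cap), "LC", (w1, w2), config.alpha_d)


def fc_threshold(alpha: float, config: CombinedConfig) -> float:
    """Critical value ``C`` with ``P_H0(P1 < alpha_D, Z_FC > C) = alpha``."""
    if alpha >= config.alpha_d:
        raise ValueError(
            "alpha must be below alpha_d (the conditioning event has "
            f"probability alpha_d={config.alpha_d:g})"
        )
    w1, _ = config.weights()
    lo = -2.0 * w1 * math.log(config.alpha_d)
    hi = lo + 10.0
    while fisher_pvalue(hi, config).p_value > alpha:
        hi += 10.0
    return float(
        optimize.brentq(
            lambda z: fisher_pvalue(z, config).p_value - alpha, lo, hi,
            xtol=1e-12, rtol=8.9e-16,
        )
    )


def lc_threshold(alpha: float, config: CombinedConfig, exact: bool = True) -> float:
    """Critical value of ``Z_LC`` at conditional level ``alpha``.

    Uses the exact conditional probability by default, which is what controls
    the per-marker type I error in a two-stage design.
    """
    cap = config.alpha_d if exact else config.alpha_d / 2.0
    if alpha >= cap:
        raise ValueError(f"alpha must be below {cap:g}")
    w1, w2 = config.weights()
    scale = 2.0 if exact else 1.0
    # the threshold may sit below the published support when alpha is close
    # to alpha_d; the integral itself is defined (and monotone) everywhere
    q = float(ndtri(1.0 - config.alpha_d / 2.0))
    lo, hi = q - 20.0, q + 10.0
    while scale * _lc_integral(hi, w1, w2, config.alpha_d) > alpha:
        hi += 5.0
    return float(
        optimize.brentq(
            lambda z: scale * _lc_integral(z, w1, w2, config.alpha_d) - alpha,
            lo, hi, xtol=1e-12, rtol=8.9e-16,
        )
    )
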