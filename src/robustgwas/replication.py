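"""Replication-stage p-values that inherit the discovery-stage selection.

Exact replication of a discovery finding re-tests the marker with the same
analytic method, the same selected genetic model (or test component) and the
same risk-allele direction.  The stage-2 p-value is therefore one-sided in
the direction the discovery stage established:

    P_x^(2) = 1 - Phi( sign(Z_x^(1)) * Z_x^(2) )

for a trend test with fixed score ``x`` (``sign(0) = +1``), and for the robust
tests the score/component is chosen by the discovery-stage record:

* MAX3 — the score with the smallest discovery single-model p-value;
* MIN2 — the additive trend if ``P_1/2^(1) <= P_chi2^(1)``, else Pearson;
* GMS/GME — the score picked by the discovery ``Z_H`` region, with the
  recessive/dominant roles exchanged when ``Z_1/2^(1) <= 0`` (the starred
  statistics, restandardised with stage-2 correlations, for GME).

Although the stage-2 p-value reuses discovery decisions, the two stages'
p-values are independent under the null: the direction signs are +/-1 with
probability one half and each model is selected with a fixed probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import math

import numpy as np
from scipy.special import ndtr

from .contingency import GenotypeCounts, catt, estimate_correlations, pearson_chi2
from .robust import (
    RobustTestResult,
    gme_stat,
    gms_select,
    max3_pvalue,
    min2_pvalue,
    min2_stat,
)

__all__ = ["StageOneRecord", "ReplicationResult", "stage_one_record", "stage2_pvalue"]


def _sign(v: float) -> float:
    """sign with sign(0) = +1."""
    return 1.0 if v >= 0 else -1.0


@dataclass(frozen=True)
class StageOneRecord:
    """Everything the replication stage inherits from discovery.

    ``signs`` / ``signs_star`` map the CATT score to the sign of the stage-1
    (starred) trend statistic; ``zh_region`` is where the stage-1 HWDTT fell
    relative to ``+-c`` ("above" / "within" / "below").
    """

    method: str
    p_value: float
    sign_z_half: float
    signs: Mapping[float, float]
    signs_star: Mapping[float, float]
    selected_score: float | None = None  # MAX3
    component: str | None = None  # MIN2
    zh_region: str | None = None  # GMS / GME
    alpha_h: float = 0.05
    c: float | None = None


@dataclass(frozen=True)
class ReplicationResult:
    method: str
    p_value: float
    statistic: float
    score: float | None = None
    component: str | None = None


_METHODS = ("CATT", "CHI2", "MAX3", "MIN2", "GMS", "GME")


def stage_one_record(
    counts: GenotypeCounts,
    method: str,
    score: float = 0.5,
    alpha_h: float = 0.05,
    b_bootstrap: int = 100_000,
    seed: int = 0,
    max3_mode: str = "bootstrap",
) -> StageOneRecord:
    """Build the discovery record for ``method`` from stage-1 counts.

    ``score`` only applies to the plain CATT.  The record is a pure function
    of the counts (plus bootstrap settings for MAX3), so recomputing it from
    the same table always reproduces it.
    """
    method = method.upper()
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}")
    z = {x: catt(counts, x).statistic for x in (0.0, 0.5, 1.0)}
    corr = estimate_correlations(counts)
    z_star = {
        0.0: (z[0.0] + z[0.5]) / math.sqrt(2.0 * (1.0 + corr.rho_0_half)),
        0.5: z[0.5],
        1.0: (z[1.0] + z[0.5]) / math.sqrt(2.0 * (1.0 + corr.rho_1_half)),
    }
    signs = {x: _sign(v) for x, v in z.items()}
    signs_star = {x: _sign(v) for x, v in z_star.items()}
    common = dict(
        sign_z_half=_sign(z[0.5]),
        signs=signs,
        signs_star=signs_star,
        alpha_h=alpha_h,
    )
    if method == "CATT":
        res = catt(counts, score)
        return StageOneRecord(
            method=method, p_value=res.p_value, selected_score=score, **common
        )
    if method == "CHI2":
        return StageOneRecord(
            method=method, p_value=pearson_chi2(counts).p_value, **common
        )
    if method == "MAX3":
        res = max3_pvalue(counts, b=b_bootstrap, seed=seed, mode=max3_mode)
        # the score with the smallest stage-1 single-model p-value
        return StageOneRecord(
            method=method,
            p_value=res.p_value,
            selected_score=res.selected_score,
            **common,
        )
    if method == "MIN2":
        res = min2_stat(counts)
        return StageOneRecord(
            method=method,
            p_value=min2_pvalue(res.statistic),
            component=res.component,
            **common,
        )
    selector = gms_select if method == "GMS" else gme_stat
    res: RobustTestResult = selector(counts, alpha_h)
    from .robust import gme_pvalue, gms_pvalue  # local import avoids cycle at module load

    pfun = gms_pvalue if method == "GMS" else gme_pvalue
    return StageOneRecord(
        method=method,
        p_value=pfun(res, corr),
        selected_score=res.selected_score,
        zh_region=res.zh_region,
        c=res.c,
        **common,
    )


def _one_sided(sign1: float, z2: float) -> float:
    return float(1.0 - ndtr(sign1 * z2))


def _gms_score(record: StageOneRecord) -> float:
    """Stage-2 CATT score implied by the stage-1 Z_H region and Z_1/2 sign."""
    if record.zh_region is None:
        raise ValueError("record lacks the stage-1 Z_H region")
    if record.sign_z_half > 0:
        return {"above": 0.0, "within": 0.5, "below": 1.0}[record.zh_region]
    return {"above": 1.0, "within": 0.5, "below": 0.0}[record.zh_region]


def stage2_pvalue(record: StageOneRecord, counts2: GenotypeCounts) -> ReplicationResult:
    """One-sided replication p-value of ``counts2`` given the discovery record."""
    method = record.method
    if method == "CHI2":
        res = pearson_chi2(counts2)
        return ReplicationResult(method, res.p_value, res.statistic)
    if method == "MIN2":
        if record.component is None:
            raise ValueError("MIN2 record lacks the selected component")
        if record.component == "additive":
            z2 = catt(counts2, 0.5).statistic
            return ReplicationResult(
                method, _one_sided(record.signs[0.5], z2), z2, score=0.5,
                component="additive",
            )
        res = pearson_chi2(counts2)
        return ReplicationResult(method, res.p_value, res.statistic, component="chi2")
    if method in ("CATT", "MAX3"):
        x = record.selected_score
        if x is None:
            raise ValueError(f"{method} record lacks the selected score")
        z2 = catt(counts2, x).statistic
        return ReplicationResult(method, _one_sided(record.signs[x], z2), z2, score=x)
    if method == "GMS":
        x = _gms_score(record)
        z2 = catt(counts2, x).statistic
        return ReplicationResult(method, _one_sided(record.signs[x], z2), z2, score=x)
    if method == "GME":
        x = _gms_score(record)
        z = {y: catt(counts2, y).statistic for y in (0.0, 0.5, 1.0)}
        corr2 = estimate_correlations(counts2)  # stage-2 standardisation
        rho = {0.0: corr2.rho_0_half, 0.5: 1.0, 1.0: corr2.rho_1_half}[x]
        z2 = (z[x] + z[0.5]) / math.sqrt(2.0 * (1.0 + rho))
        return ReplicationResult(
            method, _one_sided(record.signs_star[x], z2), z2, score=x
        )
    raise ValueError(f"unknown method {method!r}")
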