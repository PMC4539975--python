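"""Two-stage case-control genotype simulator and type-I-error / power engine.

A marker is parametrised by the B-allele frequency ``p`` (MAF), an inbreeding
coefficient ``F`` controlling Hardy-Weinberg departure, disease prevalence
``K`` and genotype relative risks ``lambda_1 = f1/f0``, ``lambda_2 = f2/f0``
constrained by the genetic model (recessive: ``lambda_1 = 1``; additive:
``lambda_1 = (1 + lambda_2)/2``; multiplicative: ``lambda_1 = sqrt(lambda_2)``;
dominant: ``lambda_1 = lambda_2``).  Penetrances are solved from prevalence,
then inverted by Bayes' rule into case and control genotype distributions from
which each stage's tables are drawn as independent multinomials.

``run_scenario`` reproduces the two-stage design: every marker is tested at
stage 1 with a chosen method; markers with ``P1 < alpha_D`` proceed to stage
2, where three declaration strategies are evaluated at per-marker level
``alpha / M`` (Bonferroni over the M markers):

* REP — replication-based: ``P2 < (alpha/M) / alpha_D`` (stage independence
  under the null makes the product calibration exact);
* FC  — Fisher combination above its conditional critical value;
* LC  — inverse-normal combination above its conditional critical value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr, ndtri

from .combine import CombinedConfig, fc_threshold, lc_threshold
from .contingency import (
    GenotypeCounts,
    _abt_z,
    _catt_z,
    _correlations,
    _hwdtt_z,
    _pearson_t,
    _two_sided,
)
from .robust import _max3_box, _min2_pvalue_batch, _selection_survival_batch

__all__ = [
    "SimulationScenario",
    "SimulationSummary",
    "genotype_freqs",
    "penetrance_solve",
    "case_control_probs",
    "sample_two_stage",
    "run_scenario",
]

_MODEL_LAMBDA1 = {
    "REC": lambda l2: 1.0,
    "ADD": lambda l2: (1.0 + l2) / 2.0,
    "MUL": lambda l2: math.sqrt(l2),
    "DOM": lambda l2: l2,
}

ALL_TESTS = ("CATT", "CHI2", "MAX3", "MIN2", "GMS", "GME")
STRATEGIES = ("REP", "FC", "LC")


def genotype_freqs(maf: float, f: float = 0.0) -> np.ndarray:
    """Genotype frequencies ``(g0, g1, g2)`` under the inbreeding model.

    ``g2 = p^2 + F p (1-p)`` etc.; the implied HWD coefficient is
    ``Delta = g2 - (g1/2 + g2)^2 = F p (1 - p)``.
    """
    if not 0.0 < maf < 1.0:
        raise ValueError(f"maf must be in (0, 1), got {maf}")
    p = maf
    g = np.array(
        [
            (1.0 - p) ** 2 + f * p * (1.0 - p),
            2.0 * p * (1.0 - p) * (1.0 - f),
            p * p + f * p * (1.0 - p),
        ]
    )
    if np.any(g < 0.0):
        raise ValueError(f"F={f} gives negative genotype frequencies at maf={maf}")
    return g


def penetrance_solve(model: str, lambda2: float, k: float, freqs: np.ndarray) -> np.ndarray:
    """Penetrances ``(f0, f1, f2)`` matching prevalence ``k`` and the GRRs."""
    model = model.upper()
    if model not in _MODEL_LAMBDA1:
        raise ValueError(f"unknown genetic model {model!r}")
    if lambda2 < 1.0:
        raise ValueError(f"lambda2 must be >= 1, got {lambda2}")
    if not 0.0 < k < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {k}")
    l1 = _MODEL_LAMBDA1[model](lambda2)
    lam = np.array([1.0, l1, lambda2])
    f0 = k / float((lam * np.asarray(freqs)).sum())
    f = lam * f0
    if np.any(f > 1.0):
        raise ValueError(
            f"scenario infeasible: penetrance exceeds 1 (model={model}, "
            f"lambda2={lambda2}, K={k})"
        )
    return f


def case_control_probs(f: np.ndarray, freqs: np.ndarray, k: float):
    """Bayes inversion: genotype distributions in cases and in controls."""
    f = np.asarray(f, dtype=float)
    g = np.asarray(freqs, dtype=float)
    p = f * g / k
    q = (1.0 - f) * g / (1.0 - k)
    return p / p.sum(), q / q.sum()


@dataclass(frozen=True)
class SimulationScenario:
    """Complete specification of a two-stage simulation experiment.

    ``lambda2 = 1`` is the null; ``lambda2_stage2`` allows between-stage
    effect heterogeneity (defaults to ``lambda2``).  ``pi_s`` is the fraction
    of each group allocated to the discovery stage.
    """

    maf: float = 0.3
    hwd_f: float = 0.0
    prevalence: float = 0.1
    model: str = "ADD"
    lambda2: float = 1.0
    lambda2_stage2: float | None = None
    n_cases: int = 1500
    n_controls: int = 1500
    pi_s: float = 0.5
    n_markers: int = 10
    alpha: float = 0.05
    alpha_d: float = 0.05
    alpha_h: float = 0.05
    n_reps: int = 20_000
    seed: int = 0
    tests: Sequence[str] = ALL_TESTS
    weight_scheme: str = "equal"

    def __post_init__(self) -> None:
        for name in ("alpha", "alpha_d", "alpha_h"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0.0 < self.pi_s < 1.0:
            raise ValueError(f"pi_s must be in (0, 1), got {self.pi_s}")
        if self.n_markers < 1 or self.n_reps < 1:
            raise ValueError("n_markers and n_reps must be >= 1")
        if self.alpha / self.n_markers > self.alpha_d:
            raise ValueError("per-marker level alpha/M above alpha_d is not attainable")
        unknown = set(t.upper() for t in self.tests) - set(ALL_TESTS)
        if unknown:
            raise ValueError(f"unknown tests {sorted(unknown)}")

    @property
    def stage_sizes(self) -> tuple[int, int, int, int]:
        """(cases1, controls1, cases2, controls2)."""
        r1 = int(round(self.pi_s * self.n_cases))
        s1 = int(round(self.pi_s * self.n_controls))
        if min(r1, s1, self.n_cases - r1, self.n_controls - s1) < 1:
            raise ValueError("stage split leaves an empty group")
        return r1, s1, self.n_cases - r1, self.n_controls - s1

    def stage_probs(self, stage: int):
        """Case/control genotype distributions for the given stage (1 or 2)."""
        g = genotype_freqs(self.maf, self.hwd_f)
        l2 = self.lambda2 if stage == 1 else (
            self.lambda2 if self.lambda2_stage2 is None else self.lambda2_stage2
        )
        f = penetrance_solve(self.model, l2, self.prevalence, g)
        return case_control_probs(f, g, self.prevalence)


@dataclass(frozen=True)
class SimulationSummary:
    """Per test x strategy empirical rejection proportions."""

    scenario: SimulationScenario
    proportions: pd.DataFrame  # index: test, columns: REP / FC / LC
    n_marker_tests: int

    @property
    def standard_errors(self) -> pd.DataFrame:
        p = self.proportions
        return np.sqrt(p * (1.0 - p) / self.n_marker_tests)


def _rep_rng(seed: int, rep: int) -> np.random.Generator:
    return np.random.default_rng((int(seed), int(rep)))


def sample_two_stage(scenario: SimulationScenario, rep_index: int):
    """Draw one replicate: per marker a (stage-1, stage-2) pair of tables.

    Deterministic given ``(scenario.seed, rep_index)``.
    """
    c1, c2 = _draw_replicate(scenario, rep_index)
    out = []
    for j in range(scenario.n_markers):
        a, b, c, d = c1[0][j], c1[1][j], c2[0][j], c2[1][j]
        out.append(
            (
                GenotypeCounts(*(int(v) for v in a), *(int(v) for v in b)),
                GenotypeCounts(*(int(v) for v in c), *(int(v) for v in d)),
            )
        )
    return out


def _draw_replicate(scenario: SimulationScenario, rep_index: int):
    rng = _rep_rng(scenario.seed, rep_index)
    r1, s1, r2, s2 = scenario.stage_sizes
    p1v, q1v = scenario.stage_probs(1)
    p2v, q2v = scenario.stage_probs(2)
    m = scenario.n_markers
    return (
        (rng.multinomial(r1, p1v, size=m), rng.multinomial(s1, q1v, size=m)),
        (rng.multinomial(r2, p2v, size=m), rng.multinomial(s2, q2v, size=m)),
    )


def _draw_batch(scenario: SimulationScenario):
    """All replicates stacked to shape (n_reps * M, 3) per group per stage."""
    shapes = (scenario.n_reps * scenario.n_markers, 3)
    case1 = np.empty(shapes)
    ctrl1 = np.empty(shapes)
    case2 = np.empty(shapes)
    ctrl2 = np.empty(shapes)
    m = scenario.n_markers
    for rep in range(scenario.n_reps):
        (a, b), (c, d) = _draw_replicate(scenario, rep)
        sl = slice(rep * m, (rep + 1) * m)
        case1[sl], ctrl1[sl], case2[sl], ctrl2[sl] = a, b, c, d
    return case1, ctrl1, case2, ctrl2


class _StageStats:
    """Lazily computed vectorised statistics of one stage's tables."""

    def __init__(self, cases: np.ndarray, controls: np.ndarray):
        self.cases = cases
        self.controls = controls
        self._cache: dict = {}

    def z(self, x: float) -> np.ndarray:
        key = ("z", x)
        if key not in self._cache:
            with np.errstate(divide="ignore", invalid="ignore"):
                self._cache[key] = _catt_z(self.cases, self.controls, x)
        return self._cache[key]

    @property
    def z_stack(self) -> np.ndarray:
        if "z_stack" not in self._cache:
            self._cache["z_stack"] = np.stack(
                [self.z(0.0), self.z(0.5), self.z(1.0)], axis=-1
            )
        return self._cache["z_stack"]

    @property
    def chi2(self):
        if "chi2" not in self._cache:
            t, df = _pearson_t(self.cases, self.controls)
            with np.errstate(invalid="ignore"):
                p = stats.chi2.sf(t, np.maximum(df, 1))
            self._cache["chi2"] = (t, df, p)
        return self._cache["chi2"]

    @property
    def z_h(self) -> np.ndarray:
        if "z_h" not in self._cache:
            with np.errstate(divide="ignore", invalid="ignore"):
                self._cache["z_h"] = _hwdtt_z(self.cases, self.controls)
        return self._cache["z_h"]

    @property
    def corr(self):
        if "corr" not in self._cache:
            with np.errstate(divide="ignore", invalid="ignore"):
                self._cache["corr"] = _correlations(self.cases, self.controls)
        return self._cache["corr"]

    def z_star(self, x: float) -> np.ndarray:
        key = ("z_star", x)
        if key not in self._cache:
            if x == 0.5:
                self._cache[key] = self.z(0.5)
            else:
                rho = self.corr.rho_0_half if x == 0.0 else self.corr.rho_1_half
                self._cache[key] = (self.z(x) + self.z(0.5)) / np.sqrt(
                    2.0 * (1.0 + rho)
                )
        return self._cache[key]

    @property
    def z_star_stack(self) -> np.ndarray:
        if "z_star_stack" not in self._cache:
            self._cache["z_star_stack"] = np.stack(
                [self.z_star(0.0), self.z_star(0.5), self.z_star(1.0)], axis=-1
            )
        return self._cache["z_star_stack"]


def _sign(a: np.ndarray) -> np.ndarray:
    return np.where(a >= 0, 1.0, -1.0)


def _one_sided(sign1: np.ndarray, z2: np.ndarray) -> np.ndarray:
    return 1.0 - ndtr(sign1 * z2)


def _gms_selection(s1: _StageStats, c: float):
    """Selected score index (0, 1, 2) and orientation for every table."""
    pos = s1.z(0.5) > 0
    above = s1.z_h > c
    below = s1.z_h < -c
    idx_pos = np.where(above, 0, np.where(below, 2, 1))
    idx_neg = np.where(above, 2, np.where(below, 0, 1))
    return np.where(pos, idx_pos, idx_neg), pos


def _take(stack: np.ndarray, idx: np.ndarray) -> np.ndarray:
    return np.take_along_axis(stack, idx[..., None], axis=-1)[..., 0]


def _stage_pvalues(test: str, s1: _StageStats, s2: _StageStats, c: float):
    """(P1, P2) arrays for one test over all marker-replicates."""
    if test == "CATT":
        return _two_sided(s1.z(0.5)), _one_sided(_sign(s1.z(0.5)), s2.z(0.5))
    if test == "CHI2":
        return s1.chi2[2], s2.chi2[2]
    if test == "MAX3":
        t1 = np.abs(s1.z_stack).max(axis=-1)
        idx = np.abs(s1.z_stack).argmax(axis=-1)
        with np.errstate(invalid="ignore"):
            p1 = 1.0 - _max3_box(t1, s1.corr)
        p2 = _one_sided(_sign(_take(s1.z_stack, idx)), _take(s2.z_stack, idx))
        return p1, p2
    if test == "MIN2":
        p_add1 = _two_sided(s1.z(0.5))
        m = np.minimum(s1.chi2[2], p_add1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p1 = np.where(np.isfinite(m) & (m > 0), _min2_pvalue_batch(np.clip(m, 1e-300, 1.0 - 1e-12)), np.nan)
        use_add = p_add1 <= s1.chi2[2]
        p2 = np.where(use_add, _one_sided(_sign(s1.z(0.5)), s2.z(0.5)), s2.chi2[2])
        return p1, p2
    if test in ("GMS", "GME"):
        starred = test == "GME"
        idx, pos = _gms_selection(s1, c)
        stack1 = s1.z_star_stack if starred else s1.z_stack
        t1 = np.where(pos, _take(stack1, idx), -_take(stack1, idx))
        with np.errstate(invalid="ignore"):
            p1 = _selection_survival_batch(t1, s1.corr, c, starred=starred)
        stack2 = s2.z_star_stack if starred else s2.z_stack
        p2 = _one_sided(_sign(_take(stack1, idx)), _take(stack2, idx))
        return p1, p2
    raise ValueError(f"unknown test {test!r}")


def run_scenario(scenario: SimulationScenario) -> SimulationSummary:
    """Run the two-stage experiment and tabulate rejection proportions.

    The per-marker rejection proportion is the count of (replicate, marker)
    rejections divided by ``n_reps * M``; under the null it targets
    ``alpha / M``.
    """
    case1, ctrl1, case2, ctrl2 = _draw_batch(scenario)
    s1 = _StageStats(case1, ctrl1)
    s2 = _StageStats(case2, ctrl2)
    c = float(stats.norm.isf(scenario.alpha_h))
    per_marker = scenario.alpha / scenario.n_markers
    beta_rep = per_marker / scenario.alpha_d

    cfg_fc = CombinedConfig(
        scenario.alpha_d, scenario.weight_scheme, scenario.pi_s, "FC"
    )
    cfg_lc = CombinedConfig(
        scenario.alpha_d, scenario.weight_scheme, scenario.pi_s, "LC"
    )
    c_fc = fc_threshold(per_marker, cfg_fc)
    c_lc = lc_threshold(per_marker, cfg_lc, exact=True)
    w1f, w2f = cfg_fc.weights()
    w1l, w2l = cfg_lc.weights()
    norm_l = math.sqrt(w1l**2 + w2l**2)

    n_total = scenario.n_reps * scenario.n_markers
    rows = {}
    for test in (t.upper() for t in scenario.tests):
        p1, p2 = _stage_pvalues(test, s1, s2, c)
        with np.errstate(invalid="ignore", divide="ignore"):
            sel = p1 < scenario.alpha_d
            p1c = np.clip(p1, 1e-300, 1.0)
            p2c = np.clip(p2, 1e-300, 1.0 - 1e-16)
            rej_rep = sel & (p2 < beta_rep)
            z_fc = -2.0 * (w1f * np.log(p1c) + w2f * np.log(p2c))
            rej_fc = sel & (z_fc > c_fc)
            z_lc = (w1l * ndtri(1.0 - p1c / 2.0) + w2l * ndtri(1.0 - p2c)) / norm_l
            rej_lc = sel & (z_lc > c_lc)
        rows[test] = [
            np.sum(rej_rep) / n_total,
            np.sum(rej_fc) / n_total,
            np.sum(rej_lc) / n_total,
        ]
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(STRATEGIES))
    return SimulationSummary(scenario, frame, n_total)
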