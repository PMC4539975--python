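import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from robustgwas import GenotypeCounts, SimulationScenario, run_scenario
from robustgwas.simulate import _StageStats, _draw_batch, _stage_pvalues

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=60,
    derandomize=True,
    suppress_health_check=[HealthCheck.filter_too_much, HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def balanced_table():
    """A moderately associated, fully polymorphic table."""
    return GenotypeCounts(10, 10, 20, 20, 10, 10)


@pytest.fixture
def null_table():
    """Identical case/control genotype distributions."""
    return GenotypeCounts(10, 20, 30, 10, 20, 30)


@pytest.fixture(scope="session")
def null_summary_fast_tests():
    """Null two-stage design of the type-I-error study: CATT / Pearson / MIN2.

    K=0.1, MAF 0.3, F=0, 1500+1500 split 50/50, M=10, alpha=0.05 Bonferroni,
    alpha_D=0.05, 20000 replicates.
    """
    sc = SimulationScenario(tests=("CATT", "CHI2", "MIN2"), n_reps=20_000, seed=101)
    return run_scenario(sc)


@pytest.fixture(scope="session")
def null_summary_twophase_tests():
    """Same null design for MAX3 / GMS / GME at 5000 replicates."""
    sc = SimulationScenario(tests=("MAX3", "GMS", "GME"), n_reps=5_000, seed=202)
    return run_scenario(sc)


@pytest.fixture(scope="session")
def power_summaries():
    """Power scenarios: additive model, MAF 0.3, 1000+1000, 2000 replicates,
    homogeneous (1.4/1.4) and heterogeneous (1.6/1.4) genotype relative risks."""
    out = {}
    for key, l2, seed in (("hom", 1.4, 303), ("het", 1.6, 404)):
        sc = SimulationScenario(
            model="ADD",
            lambda2=l2,
            lambda2_stage2=1.4,
            n_cases=1000,
            n_controls=1000,
            n_reps=2_000,
            seed=seed,
        )
        out[key] = run_scenario(sc)
    return out


@pytest.fixture(scope="session")
def null_stage_pvalue_arrays():
    """Per-method (P1, P2) arrays plus stage-1 statistics for a single-marker
    null scenario, for independence/uniformity/branch-probability checks.

    Uses large per-group sizes: the independence/uniformity claim is
    asymptotic, and at small n the count discreteness alone fails a KS test
    with 20000 samples.
    """
    sc = SimulationScenario(
        n_cases=8000, n_controls=8000, n_markers=1, n_reps=20_000, seed=505
    )
    case1, ctrl1, case2, ctrl2 = _draw_batch(sc)
    s1 = _StageStats(case1, ctrl1)
    s2 = _StageStats(case2, ctrl2)
    from scipy import stats as sps

    c = float(sps.norm.isf(sc.alpha_h))
    out = {"s1": s1, "s2": s2, "c": c}
    for test in ("CATT", "CHI2", "MAX3", "MIN2", "GMS", "GME"):
        out[test] = _stage_pvalues(test, s1, s2, c)
    return out
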