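"""Exact count statistics and the end-to-end synthetic analysis pipeline.

The three tests used on the study's count data:

* a two-sided Fisher exact test on 2x2 tables (between-genotype
  comparisons of category counts);
* a two-sided exact binomial test of a single proportion against a 50:50
  null (chromosome identity of protein-positive spermatids);
* a two-sided unpaired t test on per-male progeny sex ratios.

Both exact tests use the "sum of outcome probabilities no larger than the
observed one" two-sided convention, with a relative tie tolerance of 1e-12
(exact-test two-sided conventions differ between packages; this one is
stated explicitly so results are reproducible).  No multiple-testing
correction is applied: per-comparison exact P values are reported.

:func:`run_full_pipeline` chains everything: generate a synthetic study,
exclude nondisjunction spermatids, run the tests, estimate the cytology
parameters and the drive strength, and forecast the population consequence
against the extinction threshold.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .drive_model import DriveParams
from .meiosis_model import (
    CytologyEstimates,
    MeiosisParams,
    drive_strength_from_cytology,
    estimate_cytology_params,
)
from .phase_analysis import ThresholdResult, analytic_threshold, classify_dynamics
from .synthetic_study import (
    PRESETS,
    ProgenyRecord,
    StudyPreset,
    SyntheticStudy,
    generate_study,
)

__all__ = [
    "TestResult",
    "DriveEstimate",
    "PipelineConfig",
    "PipelineReport",
    "fisher_exact_two_sided",
    "binomial_two_sided",
    "unpaired_t_two_sided",
    "estimate_drive_strength",
    "analyze_study",
    "run_full_pipeline",
]

logger = logging.getLogger("stellate_drive")

#: Relative tolerance for probability ties in two-sided exact tests.
TIE_REL_TOL = 1e-12


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test (all tests here are two-sided)."""

    name: str
    statistic: Optional[float]
    p_value: float
    n: tuple[int, ...]
    tails: str = "two-sided"
    df: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


@lru_cache(maxsize=4096)
def _hypergeom_pmf(n: int, r1: int, c1: int) -> tuple[np.ndarray, np.ndarray]:
    """Support and pmf of the table's conditional (hypergeometric) law."""
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    return support, pmf


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher exact test of independence on a 2x2 table.

    Conditions on both margins; the two-sided p-value sums the
    hypergeometric probabilities of every table at most as probable as the
    observed one (ties at relative tolerance ``TIE_REL_TOL``).  The
    statistic is the sample odds ratio.  Symmetric under row and column
    swaps.
    """
    a = np.asarray(table, dtype=float)
    if a.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(a < 0) or not np.all(a == np.floor(a)):
        raise ValueError("cells must be nonnegative integers")
    a = a.astype(int)
    n = int(a.sum())
    if n == 0:
        raise ValueError("empty table")
    r1 = int(a[0].sum())
    c1 = int(a[:, 0].sum())
    support, pmf = _hypergeom_pmf(n, r1, c1)
    p_obs = float(pmf[support == a[0, 0]][0])
    p = float(pmf[pmf <= p_obs * (1.0 + TIE_REL_TOL)].sum())

    if a[0, 1] * a[1, 0] > 0:
        odds: Optional[float] = (a[0, 0] * a[1, 1]) / (a[0, 1] * a[1, 0])
    elif a[0, 0] * a[1, 1] > 0:
        odds = math.inf
    else:
        odds = math.nan
    return TestResult(
        name="fisher_exact", statistic=odds, p_value=min(p, 1.0), n=(n,)
    )


@lru_cache(maxsize=1024)
def _binom_pmf(n: int, p0: float) -> np.ndarray:
    return stats.binom.pmf(np.arange(n + 1), n, p0)


def binomial_two_sided(k: int, n: int, p0: float = 0.5) -> TestResult:
    """Two-sided exact binomial test of a single proportion.

    p-value is the total probability of all outcomes whose null probability
    does not exceed that of the observed count (same tie convention as the
    Fisher test).  The statistic is the observed proportion ``k/n``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    pmf = _binom_pmf(n, p0)
    p = float(pmf[pmf <= pmf[k] * (1.0 + TIE_REL_TOL)].sum())
    return TestResult(
        name="binomial_exact", statistic=k / n, p_value=min(p, 1.0), n=(n,)
    )


def unpaired_t_two_sided(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
) -> TestResult:
    """Two-sided unpaired t test on two groups of per-male sex ratios.

    Defaults to the classic equal-variance (Student) form; set
    ``equal_var=False`` for the Welch variant.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("groups must be finite")
    if np.var(a, ddof=1) + np.var(b, ddof=1) <= 0.0:
        raise ValueError("degenerate (zero) pooled variance")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(
        name="unpaired_t" if equal_var else "welch_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(len(a), len(b)),
        df=float(res.df),
    )


@dataclass(frozen=True)
class DriveEstimate:
    """Pooled-progeny estimate of drive strength with an exact 95% CI."""

    t_hat: float
    ci: tuple[float, float]
    n_female: int
    n_male: int
    per_male_ratios: tuple[float, ...]

    @property
    def n_total(self) -> int:
        return self.n_female + self.n_male


def estimate_drive_strength(
    progeny: Sequence[ProgenyRecord], alpha: float = 0.05
) -> DriveEstimate:
    """Drive strength from pooled progeny sex counts.

    ``t_hat`` is the pooled female fraction over all assayed males (females
    arise from X-bearing sperm); the interval is exact Clopper–Pearson.
    Per-male female:male ratios are reported alongside, the unit of
    analysis for the t test.
    """
    n_f = sum(r.total_female for r in progeny)
    n_m = sum(r.total_male for r in progeny)
    total = n_f + n_m
    if total == 0:
        raise ValueError("no offspring recorded")
    ci = proportion_confint(n_f, total, alpha=alpha, method="beta")
    return DriveEstimate(
        t_hat=n_f / total,
        ci=(float(ci[0]), float(ci[1])),
        n_female=int(n_f),
        n_male=int(n_m),
        per_male_ratios=tuple(r.sex_ratio for r in progeny),
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for one end-to-end synthetic run."""

    preset: Union[str, StudyPreset] = "X^Ste200/Y"
    seed: int = 0
    z: float = 2.0
    w: float = 2.0

    def resolve_preset(self) -> StudyPreset:
        if isinstance(self.preset, StudyPreset):
            return self.preset
        return PRESETS[self.preset]


@dataclass
class PipelineReport:
    """Everything one synthetic study run produced."""

    preset_name: str
    seed: int
    z: float
    w: float
    t_true: float
    cytology: CytologyEstimates
    t_hat_cytology: float
    drive: DriveEstimate
    tests: dict[str, TestResult]
    threshold: ThresholdResult
    outcome: str
    threshold_margin: float
    excluded_nondisjunction: int

    def to_dict(self) -> dict:
        return _format_floats(dataclasses.asdict(self))

    def to_json(self) -> str:
        """Deterministic serialization: sorted keys, 12 significant digits."""
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _format_floats(obj):
    """Round floats to 12 significant digits, recursively."""
    if isinstance(obj, float):
        if math.isfinite(obj):
            return float(f"{obj:.12g}")
        return None if math.isnan(obj) else ("inf" if obj > 0 else "-inf")
    if isinstance(obj, dict):
        return {k: _format_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_format_floats(v) for v in obj]
    return obj


def analyze_study(study: SyntheticStudy, z: float = 2.0, w: float = 2.0) -> PipelineReport:
    """Run the full statistical analysis of one (synthetic) study.

    Nondisjunction spermatids are excluded before the spermatid-identity
    test, mirroring the study's stated exclusion rule.  The population
    forecast classifies the dynamics at the progeny-estimated drive
    strength (clamped into the model's admissible range) against the
    analytic threshold for the configured (z, w).
    """
    logger.info("stage=cytology preset=%s", study.preset.name)
    cyt = estimate_cytology_params(study.telophase_i, study.telophase_ii)

    n_y = study.fish.count("Y")
    n_x = study.fish.count("X")
    n_nd = study.fish.count("nondisjunction")
    logger.info("stage=fish n_scored=%d excluded_nondisjunction=%d", n_y + n_x, n_nd)
    test_fish = binomial_two_sided(n_y, n_y + n_x, p0=0.5)

    drv, ctl = study.progeny_driver, study.progeny_control
    table = [
        [sum(r.total_female for r in drv), sum(r.total_male for r in drv)],
        [sum(r.total_female for r in ctl), sum(r.total_male for r in ctl)],
    ]
    test_progeny = fisher_exact_two_sided(table)
    test_ratio = unpaired_t_two_sided(
        [r.sex_ratio for r in drv], [r.sex_ratio for r in ctl]
    )

    drive = estimate_drive_strength(drv)
    k = study.preset.meiosis.k  # killing penetrance is not a scored quantity
    t_cyt = drive_strength_from_cytology(
        MeiosisParams(p1=cyt.p1, q=cyt.q if cyt.q_defined else 0.5, p2=cyt.p2, k=k)
    )

    thr = analytic_threshold(z, w)
    t_clamped = min(max(drive.t_hat, 0.5), 1.0)
    phase = classify_dynamics(DriveParams(t=t_clamped, z=z, w=w))
    logger.info(
        "stage=forecast t_hat=%.4f threshold=%.4f outcome=%s",
        drive.t_hat, thr.t_threshold, phase.outcome,
    )

    return PipelineReport(
        preset_name=study.preset.name,
        seed=study.seed,
        z=z,
        w=w,
        t_true=study.t_true,
        cytology=cyt,
        t_hat_cytology=t_cyt,
        drive=drive,
        tests={
            "spermatid_identity_binomial": test_fish,
            "progeny_sex_fisher": test_progeny,
            "per_male_ratio_t": test_ratio,
        },
        threshold=thr,
        outcome=phase.outcome,
        threshold_margin=drive.t_hat - thr.t_threshold,
        excluded_nondisjunction=n_nd,
    )


def run_full_pipeline(config: PipelineConfig) -> PipelineReport:
    """Synthetic study -> exclusion -> tests -> estimates -> forecast."""
    preset = config.resolve_preset()
    logger.info("stage=generate preset=%s seed=%d", preset.name, config.seed)
    study = generate_study(preset, seed=config.seed)
    return analyze_study(study, z=config.z, w=config.w)


def write_report(report: PipelineReport, path: str | Path) -> None:
    Path(path).write_text(report.to_json())
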