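"""Deterministic discrete-generation dynamics of an X-linked meiotic driver.

The model follows a population carrying a driving X chromosome (written X')
that biases its own transmission through males.  Driver (X'Y) males produce
X'-bearing sperm at frequency ``t`` (the drive strength); normal (XY) males
segregate 0.5/0.5.  Females are limited either by their own number or by the
males available to fertilize them: one male can fertilize ``w`` females, and
each reproducing female leaves ``z`` offspring.  Generations are discrete and
non-overlapping, and counts are real-valued expectations — there is no
demographic stochasticity.

Per generation ``n`` the state tracks males ``M`` and females ``F``, the five
sex-chromosome genotypes (``A`` = X'Y, ``B`` = XY, ``C`` = X'X', ``D`` = X'X,
``E`` = XX), and the X' frequencies ``R`` (in males) and ``K`` (in females).
The update is a closed-form recursion: the egg pool of size ``N`` carries X'
at frequency ``K``, the sperm pool carries X' at frequency ``t·R``, X at
``(1-R)/2`` and Y at the remainder, and offspring genotype counts are the
products of those frequencies.  The induced frequency recursion is

    R' = K
    K' = K/2 + t·R / ((2t - 1)·R + 1)

which drives X' to fixation for any t > 1/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "FEMALE_LIMITED",
    "MALE_LIMITED",
    "DriveParams",
    "PopulationState",
    "Trajectory",
    "egg_number",
    "advance_counts",
    "advance_frequencies",
    "simulate_trajectory",
]

#: Regime labels: who limits reproduction this generation.
FEMALE_LIMITED = "female-limited"
MALE_LIMITED = "male-limited"

_CLIP_TOL = 1e-12


def _clip01(x: float, tol: float = _CLIP_TOL) -> float:
    """Clip a frequency to [0, 1], tolerating round-off of at most ``tol``."""
    if x < 0.0:
        if x < -tol:
            raise ValueError(f"frequency {x!r} below 0 beyond tolerance")
        return 0.0
    if x > 1.0:
        if x > 1.0 + tol:
            raise ValueError(f"frequency {x!r} above 1 beyond tolerance")
        return 1.0
    return x


@dataclass(frozen=True)
class DriveParams:
    """Control parameters of the drive model.

    Parameters
    ----------
    t
        Drive strength: frequency of X-bearing sperm produced by driver
        males.  ``t = 0.5`` is the Mendelian control; drive proper is
        ``0.5 < t <= 1``.
    z
        Reproduction index: offspring per reproducing female.  Requires
        ``z >= 2`` (``z < 2`` declines even without a driver).
    w
        Mating index: number of females one male can fertilize.  Requires
        ``w >= 2`` (promiscuous mating).
    """

    t: float
    z: float = 2.0
    w: float = 2.0

    def __post_init__(self) -> None:
        if not 0.5 <= self.t <= 1.0:
            raise ValueError(f"drive strength t={self.t} outside [0.5, 1]")
        if self.z < 2.0:
            raise ValueError(f"reproduction index z={self.z} must be >= 2")
        if self.w < 2.0:
            raise ValueError(f"mating index w={self.w} must be >= 2")


@dataclass(frozen=True)
class PopulationState:
    """Counts and X' frequencies of one generation.

    ``A + B = M`` and ``C + D + E = F`` hold up to floating-point error;
    ``R = A/M`` and ``K = (2C + D)/(2F)`` whenever the denominators are
    positive.
    """

    n: int
    M: float
    F: float
    A: float
    B: float
    C: float
    D: float
    E: float
    R: float
    K: float

    @property
    def total(self) -> float:
        return self.M + self.F

    @classmethod
    def initial(
        cls,
        m0: float = 1000.0,
        f0: float = 1000.0,
        r0: float = 1e-3,
        k0: float = 1e-3,
    ) -> "PopulationState":
        """Standard founding population.

        Genotype counts are split from the frequencies assuming random
        union (Hardy–Weinberg proportions in females); only ``R`` and ``K``
        enter the recursion, so this split is a bookkeeping convention.
        """
        if m0 < 0 or f0 < 0:
            raise ValueError("initial counts must be nonnegative")
        r0 = _clip01(r0, tol=0.0)
        k0 = _clip01(k0, tol=0.0)
        return cls(
            n=0,
            M=m0,
            F=f0,
            A=r0 * m0,
            B=(1.0 - r0) * m0,
            C=k0 * k0 * f0,
            D=2.0 * k0 * (1.0 - k0) * f0,
            E=(1.0 - k0) * (1.0 - k0) * f0,
            R=r0,
            K=k0,
        )

    def check_invariants(self, rel_tol: float = 1e-9) -> None:
        """Raise if genotype counts do not reconcile with sex totals."""
        scale = max(self.total, 1.0)
        if abs(self.A + self.B - self.M) > rel_tol * scale:
            raise AssertionError("A + B != M beyond tolerance")
        if abs(self.C + self.D + self.E - self.F) > rel_tol * scale:
            raise AssertionError("C + D + E != F beyond tolerance")


def egg_number(M: float, F: float, params: DriveParams) -> tuple[float, str]:
    """Fertilized eggs produced this generation and the limiting regime.

    With ``w·M >= F`` every female finds a mate (female-limited regime) and
    ``N = z·F``; otherwise only ``w·M`` females reproduce (male-limited) and
    ``N = z·w·M``.  The regime switch is inclusive: equality counts as
    female-limited.
    """
    if M < 0 or F < 0:
        raise ValueError("population counts must be nonnegative")
    if params.w * M >= F:
        return params.z * F, FEMALE_LIMITED
    return params.z * params.w * M, MALE_LIMITED


def advance_frequencies(R: float, K: float, t: float) -> tuple[float, float]:
    """One step of the X' frequency recursion.

    Returns ``(R', K')`` with ``R' = K`` and
    ``K' = K/2 + t·R/((2t-1)·R + 1)``.  The compact form is algebraically
    identical to the allele-counting expression
    ``[K/2 + t·R + (t - 1/2)·K·R] / [(2t-1)·R + 1]``.
    """
    if not 0.0 <= R <= 1.0:
        raise ValueError(f"R={R} outside [0, 1]")
    if not 0.0 <= K <= 1.0:
        raise ValueError(f"K={K} outside [0, 1]")
    if not 0.5 <= t <= 1.0:
        raise ValueError(f"t={t} outside [0.5, 1]")
    k_next = K / 2.0 + t * R / ((2.0 * t - 1.0) * R + 1.0)
    return K, _clip01(k_next)


def advance_counts(state: PopulationState, params: DriveParams) -> PopulationState:
    """Advance one generation of sex and genotype counts.

    The egg pool carries X' at frequency ``K``; the sperm pool carries X' at
    frequency ``t·R``, X at ``(1 - R)/2`` and Y at the rest.  Genotype counts
    in the next generation are the egg-by-sperm products scaled by the egg
    number ``N``.  An empty population is absorbed at zero.
    """
    t = params.t
    R, K = state.R, state.K
    N, _regime = egg_number(state.M, state.F, params)

    if N == 0.0:
        # Extinct (or male-less) population: absorbed all-zero state.  The
        # frequencies are carried forward through the frequency recursion so
        # they stay meaningful through the collapse.
        r_next, k_next = advance_frequencies(R, K, t)
        return PopulationState(
            n=state.n + 1, M=0.0, F=0.0, A=0.0, B=0.0, C=0.0, D=0.0, E=0.0,
            R=r_next, K=k_next,
        )

    M1 = (0.5 - t) * N * R + N / 2.0
    F1 = (t - 0.5) * N * R + N / 2.0
    A1 = (0.5 - t) * N * K * R + N * K / 2.0
    B1 = (0.5 - t) * N * R + (t - 0.5) * N * K * R - N * K / 2.0 + N / 2.0
    C1 = t * N * K * R
    D1 = N * K / 2.0 + t * N * R - (0.5 + t) * N * K * R
    E1 = N * (1.0 - K) * (1.0 - R) / 2.0

    if M1 > 0.0:
        R1 = _clip01(A1 / M1)
    else:
        # M' = 0 only at t = 1, R = 1; R' = K is the algebraic limit.
        R1 = K
    if F1 > 0.0:
        K1 = _clip01((2.0 * C1 + D1) / (2.0 * F1))
    else:
        K1 = advance_frequencies(R, K, t)[1]

    return PopulationState(
        n=state.n + 1, M=M1, F=F1, A=A1, B=B1, C=C1, D=D1, E=E1, R=R1, K=K1
    )


@dataclass
class Trajectory:
    """An ordered run of generations with per-step summaries.

    ``change_rate[i]`` is ``Total_{i+1}/Total_i`` and ``regime[i]`` is the
    regime of the step leaving generation ``i`` (both of length
    ``len(states) - 1``); ``sex_ratio[i]`` is ``M_i/F_i`` per state
    (``inf`` when ``F_i = 0``).  ``outcome`` is one of ``"expansion"``,
    ``"steady"``, ``"extinction"`` or ``"undetermined"``, with
    ``outcome_generation`` the generation at which the criterion was met
    (``None`` when undetermined).
    """

    states: list[PopulationState]
    change_rate: list[float]
    sex_ratio: list[float]
    regime: list[str]
    outcome: str
    outcome_generation: Optional[int]
    params: DriveParams = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.change_rate) != len(self.states) - 1:
            raise ValueError("change_rate must have length len(states) - 1")

    @property
    def final(self) -> PopulationState:
        return self.states[-1]

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy per-generation table (one row per state)."""
        rows = []
        for i, s in enumerate(self.states):
            rows.append(
                {
                    "n": s.n,
                    "M": s.M,
                    "F": s.F,
                    "Total": s.total,
                    "A": s.A,
                    "B": s.B,
                    "C": s.C,
                    "D": s.D,
                    "E": s.E,
                    "R": s.R,
                    "K": s.K,
                    "change_rate": self.change_rate[i] if i < len(self.change_rate) else np.nan,
                    "sex_ratio_MF": self.sex_ratio[i],
                    "regime": self.regime[i] if i < len(self.regime) else "",
                }
            )
        return pd.DataFrame(rows)


def _sex_ratio(state: PopulationState) -> float:
    if state.F > 0.0:
        return state.M / state.F
    return math.inf if state.M > 0.0 else math.nan


def simulate_trajectory(
    params: DriveParams,
    init: Optional[PopulationState] = None,
    max_generations: int = 500,
    extinction_floor: float = 1.0,
    steady_tol: float = 1e-6,
    steady_window: int = 50,
    fixation_tol: float = 1e-6,
    stationary_tol: float = 1e-9,
) -> Trajectory:
    """Iterate the recursion and classify the long-run outcome.

    Classification rules:

    * ``extinction`` — either sex drops below ``extinction_floor`` (default
      1.0: fewer than one expected individual).
    * ``steady`` — the change rate stays within ``steady_tol`` of 1 for
      ``steady_window`` consecutive generations *after* the allele frequency
      has settled (X' fixed, ``R > 1 - fixation_tol``, or the frequencies
      are stationary to ``stationary_tol``, which covers the Mendelian
      ``t = 0.5`` null).
    * ``expansion`` — the change rate stays above ``1 + steady_tol`` for
      ``steady_window`` generations after frequency settlement (transient
      pre-fixation growth does not count).
    * ``undetermined`` — ``max_generations`` reached without a verdict.

    The steady/expansion runs trigger an early stop, which also keeps long
    horizons from overflowing during unbounded growth.
    """
    if max_generations < 1:
        raise ValueError("max_generations must be >= 1")
    state = init if init is not None else PopulationState.initial()

    states = [state]
    rates: list[float] = []
    ratios = [_sex_ratio(state)]
    regimes: list[str] = []

    outcome = "undetermined"
    outcome_gen: Optional[int] = None
    steady_run = 0
    growth_run = 0

    for _ in range(max_generations):
        _, regime = egg_number(state.M, state.F, params)
        nxt = advance_counts(state, params)
        rate = nxt.total / state.total if state.total > 0.0 else 0.0

        regimes.append(regime)
        rates.append(rate)
        states.append(nxt)
        ratios.append(_sex_ratio(nxt))

        if nxt.M < extinction_floor or nxt.F < extinction_floor:
            outcome = "extinction"
            outcome_gen = nxt.n
            break

        settled = (nxt.R > 1.0 - fixation_tol) or (
            abs(nxt.R - state.R) < stationary_tol
            and abs(nxt.K - state.K) < stationary_tol
        )
        if settled and abs(rate - 1.0) < steady_tol:
            steady_run += 1
        else:
            steady_run = 0
        if settled and rate > 1.0 + steady_tol:
            growth_run += 1
        else:
            growth_run = 0

        state = nxt
        if steady_run >= steady_window:
            outcome = "steady"
            outcome_gen = nxt.n
            break
        if growth_run >= steady_window:
            outcome = "expansion"
            outcome_gen = nxt.n
            break

    return Trajectory(
        states=states,
        change_rate=rates,
        sex_ratio=ratios,
        regime=regimes,
        outcome=outcome,
        outcome_generation=outcome_gen,
        params=params,
    )
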