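"""Threshold, phase-classification and sweep analyses of the drive model.

For drive strength ``t`` above a critical threshold the population first
expands, then — once the driving X' approaches fixation and males become
scarce — enters a male-limited decline and goes extinct.  Below the
threshold the population keeps growing; at the threshold the long-run
change rate is exactly 1.  At X' fixation the male-limited step gives
``Total' = z·w·(1-t)·Total``, so the analytic threshold is

    t_threshold = 1 - 1/(z·w)

The female-limited steady-state candidate would require ``t = 1/z <= 0.5``,
contradicting drive, so the steady state only exists in the male-limited
regime.  The minimum over admissible parameters (z = w = 2) is 0.75.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .drive_model import (
    DriveParams,
    PopulationState,
    Trajectory,
    advance_frequencies,
    egg_number,
    simulate_trajectory,
)

__all__ = [
    "ThresholdResult",
    "PhaseResult",
    "analytic_threshold",
    "numeric_threshold",
    "long_run_change_rate",
    "classify_dynamics",
    "fixation_generations",
    "parameter_sweep",
    "plot_trajectory",
]


@dataclass(frozen=True)
class ThresholdResult:
    """Critical drive strength for given (z, w)."""

    z: float
    w: float
    t_threshold: float
    method: str
    #: Rejected candidate from the female-limited steady state (1/z); it is
    #: always <= 0.5 and hence incompatible with drive.
    female_limited_candidate: Optional[float] = None


@dataclass(frozen=True)
class PhaseResult:
    """Outcome classification of one (t, z, w) point."""

    t: float
    z: float
    w: float
    outcome: str
    transition_generation: Optional[int]
    extinction_generation: Optional[int]
    final_sex_ratio: float


def analytic_threshold(z: float, w: float) -> ThresholdResult:
    """Closed-form extinction threshold ``1 - 1/(z·w)``.

    Also exposes (and sanity-checks) the rejected female-limited candidate
    ``1/z``, which is <= 0.5 for every admissible ``z``.
    """
    if z < 2.0:
        raise ValueError(f"reproduction index z={z} must be >= 2")
    if w < 2.0:
        raise ValueError(f"mating index w={w} must be >= 2")
    candidate = 1.0 / z
    if candidate > 0.5:
        raise AssertionError("female-limited candidate exceeded 0.5")
    return ThresholdResult(
        z=z,
        w=w,
        t_threshold=1.0 - 1.0 / (z * w),
        method="analytic",
        female_limited_candidate=candidate,
    )


def long_run_change_rate(
    params: DriveParams,
    init_frequency: float = 1e-3,
    fixation_tol: float = 1e-9,
    settle_generations: int = 200,
    max_freq_generations: int = 500_000,
) -> float:
    """Asymptotic per-generation population change rate.

    Runs the frequency recursion to X' fixation (``R > 1 - fixation_tol``)
    so that transient pre-fixation growth cannot contaminate the sign of the
    long-run rate, then iterates the count recursion for
    ``settle_generations`` more steps.  Counts are renormalized to unit
    total every step — the recursion is scale-free, and renormalizing keeps
    arbitrarily long growth phases inside floating-point range.
    """
    t = params.t
    R = K = init_frequency
    n = 0
    while R < 1.0 - fixation_tol:
        R, K = advance_frequencies(R, K, t)
        n += 1
        if n > max_freq_generations:
            raise RuntimeError(
                f"frequency recursion did not fix within {max_freq_generations} generations"
            )

    m, f = 0.5, 0.5
    rate = 1.0
    for _ in range(settle_generations):
        N, _regime = egg_number(m, f, params)
        m1 = (0.5 - t) * N * R + N / 2.0
        f1 = (t - 0.5) * N * R + N / 2.0
        total = m1 + f1
        if total <= 0.0:
            return 0.0
        rate = total / (m + f)
        m, f = m1 / total, f1 / total
        R, K = advance_frequencies(R, K, t)
    return rate


def numeric_threshold(
    z: float,
    w: float,
    search_tol: float = 1e-6,
    max_iterations: int = 200,
    **rate_kwargs,
) -> ThresholdResult:
    """Extinction threshold by bisection on the long-run log change rate.

    The long-run rate exceeds 1 below the threshold and falls short of it
    above, so the sign of its log brackets the boundary.  Agrees with
    :func:`analytic_threshold` to ``search_tol``.
    """
    if search_tol <= 0.0:
        raise ValueError("search_tol must be positive")
    analytic_threshold(z, w)  # validates z, w
    lo, hi = 0.5, 1.0
    iterations = 0
    while hi - lo > search_tol:
        iterations += 1
        if iterations > max_iterations:
            raise RuntimeError("bisection failed to converge")
        mid = 0.5 * (lo + hi)
        rate = long_run_change_rate(DriveParams(mid, z, w), **rate_kwargs)
        if rate <= 0.0 or math.log(rate) < 0.0:
            hi = mid
        else:
            lo = mid
    return ThresholdResult(
        z=z, w=w, t_threshold=0.5 * (lo + hi), method="numeric"
    )


def _transition_generation(
    trajectory: Trajectory, tol: float = 1e-6
) -> Optional[int]:
    """First generation at which the change rate crosses 1 downward."""
    seen_growth = False
    for i, rate in enumerate(trajectory.change_rate):
        if rate > 1.0 + tol:
            seen_growth = True
        elif seen_growth and rate < 1.0 - tol:
            return trajectory.states[i].n
    return None


def classify_dynamics(
    params: DriveParams,
    horizon: int = 500,
    extinction_floor: float = 1.0,
    steady_tol: float = 1e-6,
    steady_window: int = 50,
    init: Optional[PopulationState] = None,
) -> PhaseResult:
    """Run a trajectory from the standard start and label its outcome."""
    traj = simulate_trajectory(
        params,
        init=init,
        max_generations=horizon,
        extinction_floor=extinction_floor,
        steady_tol=steady_tol,
        steady_window=steady_window,
    )
    return PhaseResult(
        t=params.t,
        z=params.z,
        w=params.w,
        outcome=traj.outcome,
        transition_generation=_transition_generation(traj, tol=steady_tol),
        extinction_generation=(
            traj.outcome_generation if traj.outcome == "extinction" else None
        ),
        final_sex_ratio=traj.sex_ratio[-1],
    )


def fixation_generations(
    t: float,
    epsilon: float = 1e-6,
    init_frequency: float = 1e-3,
    max_generations: int = 1_000_000,
) -> int:
    """Generations until the driving X' reaches frequency ``1 - epsilon``.

    Iterates the frequency recursion from ``R = K = init_frequency`` and
    returns the smallest ``n`` with ``R_n >= 1 - epsilon``.  Finite for any
    ``t > 0.5``; weaker drivers fix more slowly but still fix.  ``t = 0.5``
    never fixes and is rejected.
    """
    if not 0.5 < t <= 1.0:
        raise ValueError(f"fixation requires drive, t in (0.5, 1]; got {t}")
    if not 0.0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    if not 0.0 < init_frequency < 1.0:
        raise ValueError("init_frequency must be in (0, 1)")
    R = K = init_frequency
    n = 0
    while R < 1.0 - epsilon:
        R, K = advance_frequencies(R, K, t)
        n += 1
        if n > max_generations:
            raise RuntimeError("fixation not reached within max_generations")
    return n


def parameter_sweep(
    t_grid: Sequence[float],
    z_grid: Sequence[float] = (2.0,),
    w_grid: Sequence[float] = (2.0,),
    horizon: int = 500,
    **classify_kwargs,
) -> pd.DataFrame:
    """Classify every (t, z, w) combination into a tidy long-format table."""
    if not len(t_grid) or not len(z_grid) or not len(w_grid):
        raise ValueError("grids must be non-empty")
    rows = []
    for z in z_grid:
        for w in w_grid:
            for t in t_grid:
                res = classify_dynamics(
                    DriveParams(t=t, z=z, w=w), horizon=horizon, **classify_kwargs
                )
                rows.append(
                    {
                        "t": res.t,
                        "z": res.z,
                        "w": res.w,
                        "outcome": res.outcome,
                        "transition_generation": res.transition_generation,
                        "extinction_generation": res.extinction_generation,
                        "final_sex_ratio": res.final_sex_ratio,
                    }
                )
    return pd.DataFrame(rows)


def plot_trajectory(trajectory: Trajectory, path: str) -> None:
    """Save a population-size / sex-ratio plot for one trajectory."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = trajectory.to_dataframe()
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(7, 6))
    ax1.plot(df["n"], df["F"], label="females", color="tab:blue")
    ax1.plot(df["n"], df["M"], label="males", color="tab:red")
    ax1.set_yscale("log")
    ax1.set_ylabel("count")
    ax1.legend()
    ax2.plot(df["n"], df["sex_ratio_MF"], color="black")
    ax2.set_xlabel("generation")
    ax2.set_ylabel("M/F ratio")
    title = f"t={trajectory.params.t}, z={trajectory.params.z}, w={trajectory.params.w}"
    ax1.set_title(f"{title} — {trajectory.outcome}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
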