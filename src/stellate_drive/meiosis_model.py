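"""Mechanistic model of sequential asymmetric meiotic segregation.

A toxic X-encoded protein (Ste) is present in every primary spermatocyte.
During meiosis I it segregates asymmetrically into one secondary
spermatocyte with probability ``p1``, and when it does so it cosegregates
with the Y chromosome with probability ``q``; a symmetric division leaves
both secondaries carrying the protein.  During meiosis II each
protein-carrying secondary spermatocyte again divides asymmetrically with
probability ``p2`` (independently of which sex chromosome it carries),
leaving one of its two spermatids protein-free.  A protein-carrying
spermatid then fails with penetrance ``k``.

One meiosis yields four spermatids: two X-bearing and two Y-bearing.  The
expected number of protein-positive spermatids per chromosome class is

    E[(Y, Ste+)] = (2 - p2) · (p1·q + 1 - p1)
    E[(X, Ste+)] = (2 - p2) · (p1·(1 - q) + 1 - p1)

and the drive strength realized through killing is
``t = survX / (survX + survY)`` with ``surv = 2 - k·E[Ste+]`` per class.
In the idealized limit (p1 = q = p2 = k = 1) a meiosis delivers two
X-bearing and one Y-bearing functional sperm, hence t = 2/3 — the second
asymmetric division halves the cost to Y-bearing sperm and caps the drive
well below completeness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "MeiosisParams",
    "SpermatidComposition",
    "MeiosisSample",
    "CytologyEstimates",
    "expected_spermatid_composition",
    "fraction_Y_among_Ste",
    "drive_strength_from_cytology",
    "simulate_meioses",
    "estimate_cytology_params",
]


@dataclass(frozen=True)
class MeiosisParams:
    """Cytological probabilities of the segregation mechanism.

    p1 : probability meiosis I segregates the protein asymmetrically.
    q  : probability the protein cosegregates with the Y chromosome, given
         an asymmetric meiosis I.
    p2 : probability meiosis II segregates the protein asymmetrically
         (chromosome-independent: identical for X-X and Y-Y divisions).
    k  : penetrance of killing — probability a protein-carrying spermatid
         fails to become functional sperm.
    """

    p1: float
    q: float
    p2: float
    k: float = 1.0

    def __post_init__(self) -> None:
        for name in ("p1", "q", "p2", "k"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class SpermatidComposition:
    """Expected spermatid counts per meiosis, by chromosome and protein."""

    x_ste: float
    x_noste: float
    y_ste: float
    y_noste: float

    @property
    def total(self) -> float:
        return self.x_ste + self.x_noste + self.y_ste + self.y_noste

    @property
    def x_total(self) -> float:
        return self.x_ste + self.x_noste

    @property
    def y_total(self) -> float:
        return self.y_ste + self.y_noste

    def as_dict(self) -> dict[str, float]:
        return {
            "x_ste": self.x_ste,
            "x_noste": self.x_noste,
            "y_ste": self.y_ste,
            "y_noste": self.y_noste,
        }


def expected_spermatid_composition(params: MeiosisParams) -> SpermatidComposition:
    """Closed-form expected composition of the four spermatids.

    A protein-carrying secondary spermatocyte contributes ``2 - p2``
    expected protein-positive spermatids (1 if meiosis II is asymmetric,
    2 if symmetric); a protein-free secondary contributes none.  The Y-side
    secondary carries protein with probability ``p1·q + (1 - p1)`` and the
    X-side with ``p1·(1 - q) + (1 - p1)``.
    """
    p1, q, p2 = params.p1, params.q, params.p2
    y_ste = (2.0 - p2) * (p1 * q + 1.0 - p1)
    x_ste = (2.0 - p2) * (p1 * (1.0 - q) + 1.0 - p1)
    return SpermatidComposition(
        x_ste=x_ste, x_noste=2.0 - x_ste, y_ste=y_ste, y_noste=2.0 - y_ste
    )


def fraction_Y_among_Ste(params: MeiosisParams) -> float:
    """Expected fraction of protein-positive spermatids that are Y-bearing.

    Equals ``(1 - p1 + p1·q) / (2 - p1)``; the meiosis-II factor ``2 - p2``
    cancels between numerator and denominator, so the fraction carries no
    information about ``p2``.
    """
    denom = 2.0 - params.p1
    total_ste = (2.0 - params.p2) * denom
    if total_ste <= 0.0:
        raise ValueError("no protein-positive spermatids; fraction undefined")
    return (1.0 - params.p1 + params.p1 * params.q) / denom


def drive_strength_from_cytology(params: MeiosisParams) -> float:
    """Drive strength implied by the segregation probabilities.

    Surviving sperm per meiosis: ``2 - k·E[Ste+]`` for each chromosome
    class; ``t`` is the X share of survivors.  ``t = 0.5`` whenever killing
    is absent (k = 0) or segregation has no chromosome preference
    (q = 0.5).
    """
    comp = expected_spermatid_composition(params)
    surv_x = 2.0 - params.k * comp.x_ste
    surv_y = 2.0 - params.k * comp.y_ste
    total = surv_x + surv_y
    if total <= 0.0:
        raise ValueError("all spermatids killed; drive strength undefined")
    return surv_x / total


@dataclass(frozen=True)
class MeiosisSample:
    """Monte Carlo aggregate over many meioses.

    ``counts`` is the produced spermatid tally per class; ``surviving``
    applies per-spermatid killing of protein-positive spermatids with
    penetrance ``k``.
    """

    n_meioses: int
    seed: int
    counts: dict[str, int]
    surviving: dict[str, int]

    def frequencies(self) -> dict[str, float]:
        total = 4 * self.n_meioses
        return {cls: c / total for cls, c in self.counts.items()}


def simulate_meioses(
    params: MeiosisParams, n_meioses: int, seed: int
) -> MeiosisSample:
    """Sample the branching model for ``n_meioses`` independent meioses.

    Per meiosis: one Bernoulli(p1) draw for meiosis-I asymmetry, one
    Bernoulli(q) draw for the cosegregation side, one Bernoulli(p2) draw
    per secondary spermatocyte for meiosis-II asymmetry, and one
    Bernoulli(k) killing draw per protein-positive spermatid.  Deterministic
    under a fixed seed.
    """
    if n_meioses < 1:
        raise ValueError("n_meioses must be >= 1")
    rng = np.random.default_rng(seed)
    p1, q, p2, k = params.p1, params.q, params.p2, params.k

    asym = rng.random(n_meioses) < p1
    coseg_y = rng.random(n_meioses) < q
    # Protein status of the Y-side / X-side secondary spermatocyte.
    y_sec = np.where(asym, coseg_y, True)
    x_sec = np.where(asym, ~coseg_y, True)
    # Meiosis II asymmetry, drawn independently for the two secondaries.
    y_asym2 = rng.random(n_meioses) < p2
    x_asym2 = rng.random(n_meioses) < p2

    y_ste = np.where(y_sec, np.where(y_asym2, 1, 2), 0)
    x_ste = np.where(x_sec, np.where(x_asym2, 1, 2), 0)

    killed_y = rng.binomial(y_ste, k)
    killed_x = rng.binomial(x_ste, k)

    n_y_ste = int(y_ste.sum())
    n_x_ste = int(x_ste.sum())
    counts = {
        "x_ste": n_x_ste,
        "x_noste": 2 * n_meioses - n_x_ste,
        "y_ste": n_y_ste,
        "y_noste": 2 * n_meioses - n_y_ste,
    }
    surviving = {
        "x_ste": n_x_ste - int(killed_x.sum()),
        "x_noste": counts["x_noste"],
        "y_ste": n_y_ste - int(killed_y.sum()),
        "y_noste": counts["y_noste"],
    }
    return MeiosisSample(
        n_meioses=n_meioses, seed=seed, counts=counts, surviving=surviving
    )


@dataclass(frozen=True)
class CytologyEstimates:
    """Binomial MLEs of (p1, q, p2) with exact 95% confidence intervals."""

    p1: float
    p1_ci: tuple[float, float]
    q: Optional[float]
    q_ci: Optional[tuple[float, float]]
    p2: float
    p2_ci: tuple[float, float]
    n_mi: int
    n_mi_asymmetric: int
    n_mii: int
    q_defined: bool = True


def _counts_of(table: Union[Mapping[str, int], object]) -> Mapping[str, int]:
    counts = getattr(table, "counts", table)
    if not isinstance(counts, Mapping):
        raise TypeError("expected a mapping of category counts or a ScoringTable")
    return counts


def _mi_breakdown(counts: Mapping[str, int]) -> tuple[int, int, int]:
    """(n_total, n_asymmetric, n_coseg_Y) from a telophase-I table."""
    if "asymmetric_coseg_Y" in counts:
        n_y = int(counts["asymmetric_coseg_Y"])
        n_asym = n_y + int(counts.get("asymmetric_coseg_X", 0))
    else:
        n_asym = int(counts["asymmetric"])
        n_y = int(counts.get("coseg_Y", 0))
    n_total = n_asym + int(counts.get("symmetric", 0))
    return n_total, n_asym, n_y


def estimate_cytology_params(
    telophase_i: Union[Mapping[str, int], object],
    telophase_ii: Union[Mapping[str, int], object],
    alpha: float = 0.05,
) -> CytologyEstimates:
    """Estimate (p1, q, p2) from scored telophase tables.

    The MLE of each binomial proportion is the observed fraction; intervals
    are exact Clopper–Pearson at level ``1 - alpha``.  ``q`` is estimated
    only among asymmetric meiosis-I cells and is flagged undefined when no
    asymmetric cell was scored.
    """
    mi = _counts_of(telophase_i)
    mii = _counts_of(telophase_ii)
    n_mi, n_asym, n_y = _mi_breakdown(mi)
    n_mii_asym = int(mii["asymmetric"])
    n_mii = n_mii_asym + int(mii.get("symmetric", 0))
    if n_mi <= 0 or n_mii <= 0:
        raise ValueError("telophase tables must contain scored cells")
    if min(n_mi, n_asym, n_y, n_mii_asym) < 0:
        raise ValueError("counts must be nonnegative")

    p1_hat = n_asym / n_mi
    p1_ci = proportion_confint(n_asym, n_mi, alpha=alpha, method="beta")
    p2_hat = n_mii_asym / n_mii
    p2_ci = proportion_confint(n_mii_asym, n_mii, alpha=alpha, method="beta")

    if n_asym > 0:
        q_hat: Optional[float] = n_y / n_asym
        q_ci: Optional[tuple[float, float]] = tuple(
            proportion_confint(n_y, n_asym, alpha=alpha, method="beta")
        )
        q_defined = True
    else:
        q_hat, q_ci, q_defined = None, None, False

    return CytologyEstimates(
        p1=p1_hat,
        p1_ci=tuple(p1_ci),
        q=q_hat,
        q_ci=q_ci,
        p2=p2_hat,
        p2_ci=tuple(p2_ci),
        n_mi=n_mi,
        n_mi_asymmetric=n_asym,
        n_mii=n_mii,
        q_defined=q_defined,
    )
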