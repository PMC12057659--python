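"""Seeded generators for synthetic cytology and progeny datasets.

These generators emulate the statistical structure of the study's scoring
assays so every downstream analysis runs without external data:

* per-cell telophase-I/II scoring tables (asymmetric vs symmetric protein
  segregation; for telophase I, which chromosome the protein cosegregated
  with);
* X/Y identity of protein-positive spermatids scored by FISH, including a
  low rate (at most a few percent) of nondisjunction (XY or nullo)
  spermatids that downstream tests must exclude;
* per-male progeny sex counts from ten males each mated over five 5-day
  periods, with an optional ageing trend in the female fraction.

Every table records its seed and generating parameters, so fixtures are
self-documenting and exactly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .meiosis_model import MeiosisParams, drive_strength_from_cytology, fraction_Y_among_Ste

__all__ = [
    "ScoringTable",
    "ProgenyRecord",
    "StudyPreset",
    "SyntheticStudy",
    "PRESETS",
    "gen_telophase_counts",
    "gen_spermatid_fish_counts",
    "gen_progeny_counts",
    "generate_study",
    "write_study",
    "read_study",
]


@dataclass(frozen=True)
class ScoringTable:
    """A per-cell (or per-spermatid) scoring table.

    ``counts`` maps category names to nonnegative integers summing to
    ``n_total``; ``params`` echoes the generating parameters.
    """

    genotype: str
    counts: dict[str, int]
    n_total: int
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("category counts must be nonnegative")
        if sum(self.counts.values()) != self.n_total:
            raise ValueError("category counts must sum to n_total")

    def count(self, category: str) -> int:
        return self.counts.get(category, 0)


@dataclass(frozen=True)
class ProgenyRecord:
    """Offspring sex counts of one assayed male across mating periods."""

    male_id: int
    genotype: str
    females: tuple[int, ...]
    males: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.females) != len(self.males):
            raise ValueError("female and male period counts must align")
        if any(c < 0 for c in self.females + self.males):
            raise ValueError("offspring counts must be nonnegative")

    @property
    def total_female(self) -> int:
        return int(sum(self.females))

    @property
    def total_male(self) -> int:
        return int(sum(self.males))

    @property
    def total(self) -> int:
        return self.total_female + self.total_male

    @property
    def sex_ratio(self) -> float:
        """X:Y (female:male) progeny ratio; inf when no male offspring."""
        if self.total_male == 0:
            return float("inf") if self.total_female > 0 else float("nan")
        return self.total_female / self.total_male

    @property
    def female_fraction(self) -> float:
        if self.total == 0:
            return float("nan")
        return self.total_female / self.total


def gen_telophase_counts(
    n_cells: int,
    p_asym: float,
    p_coseg_y: Optional[float] = None,
    stage: str = "MI",
    seed: int = 0,
    genotype: str = "synthetic",
) -> ScoringTable:
    """Binomial scoring of telophase cells.

    Meiosis I tables record the cosegregation side among asymmetric cells
    (categories ``asymmetric_coseg_Y``, ``asymmetric_coseg_X``,
    ``symmetric``); meiosis II asymmetry is chromosome-independent, so MII
    tables only split ``asymmetric`` vs ``symmetric`` and ``p_coseg_y`` is
    ignored.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0.0 <= p_asym <= 1.0:
        raise ValueError("p_asym must be in [0, 1]")
    if stage not in ("MI", "MII"):
        raise ValueError("stage must be 'MI' or 'MII'")
    rng = np.random.default_rng(seed)
    n_asym = int(rng.binomial(n_cells, p_asym))
    if stage == "MI":
        if p_coseg_y is None or not 0.0 <= p_coseg_y <= 1.0:
            raise ValueError("MI tables require p_coseg_y in [0, 1]")
        n_y = int(rng.binomial(n_asym, p_coseg_y)) if n_asym else 0
        counts = {
            "asymmetric_coseg_Y": n_y,
            "asymmetric_coseg_X": n_asym - n_y,
            "symmetric": n_cells - n_asym,
        }
        params = {"p_asym": p_asym, "p_coseg_y": p_coseg_y, "stage": stage}
    else:
        counts = {"asymmetric": n_asym, "symmetric": n_cells - n_asym}
        params = {"p_asym": p_asym, "stage": stage}
    return ScoringTable(
        genotype=genotype, counts=counts, n_total=n_cells, seed=seed, params=params
    )


def gen_spermatid_fish_counts(
    n_spermatids: int,
    meiosis_params: MeiosisParams,
    nondisjunction_rate: float = 0.02,
    seed: int = 0,
    genotype: str = "synthetic",
) -> ScoringTable:
    """Chromosome identity of scored protein-positive spermatids.

    Each spermatid is a nondisjunction product (XY or nullo) with the
    stated low rate, and otherwise Y-bearing with probability
    :func:`~stellate_drive.meiosis_model.fraction_Y_among_Ste`.  The
    nondisjunction category is kept in the table so the downstream
    exclusion rule is exercised.
    """
    if n_spermatids < 1:
        raise ValueError("n_spermatids must be >= 1")
    if not 0.0 <= nondisjunction_rate <= 1.0:
        raise ValueError("nondisjunction_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_nd = int(rng.binomial(n_spermatids, nondisjunction_rate))
    n_scored = n_spermatids - n_nd
    f_y = fraction_Y_among_Ste(meiosis_params)
    n_y = int(rng.binomial(n_scored, f_y)) if n_scored else 0
    counts = {"Y": n_y, "X": n_scored - n_y, "nondisjunction": n_nd}
    return ScoringTable(
        genotype=genotype,
        counts=counts,
        n_total=n_spermatids,
        seed=seed,
        params={
            "p1": meiosis_params.p1,
            "q": meiosis_params.q,
            "p2": meiosis_params.p2,
            "k": meiosis_params.k,
            "nondisjunction_rate": nondisjunction_rate,
            "fraction_Y": f_y,
        },
    )


def gen_progeny_counts(
    n_males: int = 10,
    t: float = 0.5,
    offspring_per_period_mean: float = 60.0,
    n_periods: int = 5,
    age_trend: float = 0.0,
    seed: int = 0,
    genotype: str = "synthetic",
) -> list[ProgenyRecord]:
    """Per-male progeny sex counts from repeated mating periods.

    Offspring per period are Poisson with the stated mean; each offspring
    is female with probability ``t`` plus ``age_trend`` per elapsed period
    (clipped to [0, 1]), mimicking the observed rise of the female fraction
    as males age.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must be in [0, 1]")
    if n_males < 1 or n_periods < 1:
        raise ValueError("n_males and n_periods must be >= 1")
    if offspring_per_period_mean < 0:
        raise ValueError("offspring_per_period_mean must be nonnegative")
    rng = np.random.default_rng(seed)
    records = []
    for male_id in range(n_males):
        females, males = [], []
        for period in range(n_periods):
            n_off = int(rng.poisson(offspring_per_period_mean))
            p_female = min(max(t + age_trend * period, 0.0), 1.0)
            n_f = int(rng.binomial(n_off, p_female)) if n_off else 0
            females.append(n_f)
            males.append(n_off - n_f)
        records.append(
            ProgenyRecord(
                male_id=male_id,
                genotype=genotype,
                females=tuple(females),
                males=tuple(males),
            )
        )
    return records


@dataclass(frozen=True)
class StudyPreset:
    """Named parameter set for a whole synthetic study.

    Presets named after genotypes are convenience fixtures whose
    segregation probabilities are drawn from the reported cytological
    ranges (asymmetry above 80%, Y-cosegregation 64–82%); they are presets,
    not measurements.
    """

    name: str
    meiosis: MeiosisParams
    nondisjunction_rate: float = 0.02
    n_cells_mi: int = 200
    n_cells_mii: int = 150
    n_spermatids: int = 300
    n_males: int = 10
    offspring_per_period_mean: float = 60.0
    n_periods: int = 5
    age_trend: float = 0.0


PRESETS: dict[str, StudyPreset] = {
    "X^Ste200/Y": StudyPreset(
        name="X^Ste200/Y",
        meiosis=MeiosisParams(p1=0.82, q=0.73, p2=0.80, k=1.0),
    ),
    "X^Ste40/Y^cry-": StudyPreset(
        name="X^Ste40/Y^cry-",
        meiosis=MeiosisParams(p1=0.80, q=0.68, p2=0.78, k=1.0),
    ),
    # Highest-probability branch of the segregation model: two functional
    # X-bearing sperm and one Y-bearing sperm per meiosis, t = 2/3.
    "idealized": StudyPreset(
        name="idealized",
        meiosis=MeiosisParams(p1=1.0, q=1.0, p2=1.0, k=1.0),
        nondisjunction_rate=0.0,
    ),
    # Killing-free null: segregation still occurs but no spermatid dies,
    # so the realized drive strength is Mendelian (0.5).
    "control": StudyPreset(
        name="control",
        meiosis=MeiosisParams(p1=0.82, q=0.5, p2=0.80, k=0.0),
    ),
}


@dataclass
class SyntheticStudy:
    """One generated study: cytology tables plus driver and control crosses."""

    preset: StudyPreset
    seed: int
    telophase_i: ScoringTable
    telophase_ii: ScoringTable
    fish: ScoringTable
    progeny_driver: list[ProgenyRecord]
    progeny_control: list[ProgenyRecord]
    t_true: float


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def generate_study(
    preset: StudyPreset | str, seed: int = 0
) -> SyntheticStudy:
    """Generate every table of a synthetic study from one master seed."""
    if isinstance(preset, str):
        preset = PRESETS[preset]
    s_mi, s_mii, s_fish, s_drv, s_ctl = _spawn_seeds(seed, 5)
    mp = preset.meiosis
    t_true = drive_strength_from_cytology(mp)
    telophase_i = gen_telophase_counts(
        preset.n_cells_mi, mp.p1, mp.q, stage="MI", seed=s_mi, genotype=preset.name
    )
    telophase_ii = gen_telophase_counts(
        preset.n_cells_mii, mp.p2, stage="MII", seed=s_mii, genotype=preset.name
    )
    fish = gen_spermatid_fish_counts(
        preset.n_spermatids,
        mp,
        nondisjunction_rate=preset.nondisjunction_rate,
        seed=s_fish,
        genotype=preset.name,
    )
    progeny_driver = gen_progeny_counts(
        n_males=preset.n_males,
        t=t_true,
        offspring_per_period_mean=preset.offspring_per_period_mean,
        n_periods=preset.n_periods,
        age_trend=preset.age_trend,
        seed=s_drv,
        genotype=preset.name,
    )
    progeny_control = gen_progeny_counts(
        n_males=preset.n_males,
        t=0.5,
        offspring_per_period_mean=preset.offspring_per_period_mean,
        n_periods=preset.n_periods,
        age_trend=preset.age_trend,
        seed=s_ctl,
        genotype="control-cross",
    )
    return SyntheticStudy(
        preset=preset,
        seed=seed,
        telophase_i=telophase_i,
        telophase_ii=telophase_ii,
        fish=fish,
        progeny_driver=progeny_driver,
        progeny_control=progeny_control,
        t_true=t_true,
    )


def _table_frame(table: ScoringTable) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"genotype": table.genotype, "category": cat, "count": cnt}
            for cat, cnt in table.counts.items()
        ]
    )


def _progeny_frame(records: list[ProgenyRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for period, (f, m) in enumerate(zip(rec.females, rec.males)):
            rows.append(
                {
                    "male_id": rec.male_id,
                    "genotype": rec.genotype,
                    "period": period,
                    "females": f,
                    "males": m,
                }
            )
    return pd.DataFrame(rows)


def write_study(study: SyntheticStudy, out_dir: str | Path) -> None:
    """Write the study as CSV tables plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _table_frame(study.telophase_i).to_csv(out / "telophase_I.csv", index=False)
    _table_frame(study.telophase_ii).to_csv(out / "telophase_II.csv", index=False)
    _table_frame(study.fish).to_csv(out / "fish_counts.csv", index=False)
    progeny = pd.concat(
        [_progeny_frame(study.progeny_driver), _progeny_frame(study.progeny_control)],
        ignore_index=True,
    )
    progeny.to_csv(out / "progeny.csv", index=False)
    manifest = {
        "preset": asdict(study.preset),
        "seed": study.seed,
        "t_true": study.t_true,
        "driver_genotype": study.preset.name,
        "control_genotype": "control-cross",
        "table_seeds": {
            "telophase_I": study.telophase_i.seed,
            "telophase_II": study.telophase_ii.seed,
            "fish_counts": study.fish.seed,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _read_table(path: Path, seed: int, params: dict) -> ScoringTable:
    df = pd.read_csv(path)
    counts = {str(r.category): int(r.count) for r in df.itertuples()}
    genotype = str(df["genotype"].iloc[0]) if len(df) else "unknown"
    return ScoringTable(
        genotype=genotype,
        counts=counts,
        n_total=int(sum(counts.values())),
        seed=seed,
        params=params,
    )


def read_study(in_dir: str | Path) -> SyntheticStudy:
    """Reload a study written by :func:`write_study`."""
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    preset_dict = dict(manifest["preset"])
    preset = StudyPreset(
        **{**preset_dict, "meiosis": MeiosisParams(**preset_dict["meiosis"])}
    )
    seeds = manifest["table_seeds"]
    telophase_i = _read_table(src / "telophase_I.csv", seeds["telophase_I"], {})
    telophase_ii = _read_table(src / "telophase_II.csv", seeds["telophase_II"], {})
    fish = _read_table(src / "fish_counts.csv", seeds["fish_counts"], {})
    progeny = pd.read_csv(src / "progeny.csv")
    records: dict[str, list[ProgenyRecord]] = {}
    for (genotype, male_id), grp in progeny.groupby(["genotype", "male_id"]):
        grp = grp.sort_values("period")
        records.setdefault(str(genotype), []).append(
            ProgenyRecord(
                male_id=int(male_id),
                genotype=str(genotype),
                females=tuple(int(x) for x in grp["females"]),
                males=tuple(int(x) for x in grp["males"]),
            )
        )
    return SyntheticStudy(
        preset=preset,
        seed=int(manifest["seed"]),
        telophase_i=telophase_i,
        telophase_ii=telophase_ii,
        fish=fish,
        progeny_driver=records[manifest["driver_genotype"]],
        progeny_control=records[manifest["control_genotype"]],
        t_true=float(manifest["t_true"]),
    )
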