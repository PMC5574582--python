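"""Open-population simulator under Pollock's robust design.

Twelve sampling periods arranged as four primary periods of three secondary
periods each.  The population is closed within a primary period; between
primary periods (after periods 3, 6 and 9) fixed numbers of individuals of
each sex emigrate to, and immigrate from, a neighbouring population that
starts with the same size and sex ratio as the study population.  Emigrants
join the neighbour pool and immigrants leave it, so residents plus neighbours
are a fixed, conserved set of individuals and anyone can migrate repeatedly.

Captures within a period are drawn only from the individuals currently
resident, with the same sex-biased weighted sampling as the closed simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .capture_data import CaptureMatrix, SexLabel
from .closed_simulator import ClosedSimConfig, _as_rng, draw_weighted_sample

__all__ = [
    "MigrationSetting",
    "OpenSimConfig",
    "OpenTruth",
    "OpenSimResult",
    "PopulationState",
    "apply_migration",
    "simulate_open",
]


@dataclass(frozen=True)
class MigrationSetting:
    """Per-open-period migration counts (emigrants out, immigrants in, by sex)."""

    males_out: int = 0
    males_in: int = 0
    females_out: int = 0
    females_in: int = 0

    def __post_init__(self):
        if min(self.males_out, self.males_in, self.females_out, self.females_in) < 0:
            raise ValueError("migration counts must be nonnegative")


@dataclass(frozen=True)
class OpenSimConfig:
    """Design of a robust-design open-population simulation."""

    starting_population: int = 300
    proportion_male: float = 0.5
    captures_per_period: int | tuple[int, int] = 40
    bias: float = 1.0
    migration: MigrationSetting = field(default_factory=MigrationSetting)
    n_primary: int = 4
    secondaries: int = 3
    seed: int | None = None

    def __post_init__(self):
        # reuse the closed-config validation for the shared knobs
        ClosedSimConfig(
            population_size=self.starting_population,
            proportion_male=self.proportion_male,
            captures_per_period=self.captures_per_period,
            bias=self.bias,
            periods=self.n_primary * self.secondaries,
        )
        if self.n_primary < 2 or self.secondaries < 1:
            raise ValueError("need >= 2 primary periods and >= 1 secondary each")

    @property
    def periods(self) -> int:
        return self.n_primary * self.secondaries

    @property
    def primary_blocks(self) -> tuple[int, ...]:
        return tuple([self.secondaries] * self.n_primary)

    @property
    def n_males(self) -> int:
        return int(round(self.starting_population * self.proportion_male))

    @property
    def n_females(self) -> int:
        return self.starting_population - self.n_males


@dataclass
class PopulationState:
    """Resident/neighbour membership over a fixed universe of individuals."""

    sex: np.ndarray  # sex label per individual in the universe
    resident: np.ndarray  # bool per individual; non-residents form the neighbour pool

    @property
    def n_resident(self) -> int:
        return int(self.resident.sum())


def apply_migration(
    state: PopulationState, setting: MigrationSetting, rng
) -> PopulationState:
    """Apply one open period's migration, mutating and returning ``state``.

    Emigration happens first (uniform choice within sex among residents), then
    immigration (uniform choice within sex from the neighbour pool, which at
    that point already contains this period's emigrants).
    """
    rng = _as_rng(rng)
    male = state.sex == SexLabel.MALE.value
    for is_male, n_out, n_in, label in (
        (True, setting.males_out, setting.males_in, "male"),
        (False, setting.females_out, setting.females_in, "female"),
    ):
        group = male if is_male else ~male
        pool = np.flatnonzero(group & state.resident)
        if n_out > len(pool):
            raise ValueError(
                f"cannot emigrate {n_out} {label}s: only {len(pool)} resident"
            )
        if n_out:
            state.resident[rng.choice(pool, size=n_out, replace=False)] = False
        pool = np.flatnonzero(group & ~state.resident)
        if n_in > len(pool):
            raise ValueError(
                f"cannot immigrate {n_in} {label}s: only {len(pool)} in the "
                "neighbouring population"
            )
        if n_in:
            state.resident[rng.choice(pool, size=n_in, replace=False)] = True
    return state


@dataclass(frozen=True)
class OpenTruth:
    """Truth record for one open-population replicate."""

    males_throughout: int  # males present in all sampling periods
    females_throughout: int
    per_period_abundance: np.ndarray  # true residents at each sampling period

    @property
    def n_throughout(self) -> int:
        return self.males_throughout + self.females_throughout

    @property
    def sex_ratio_throughout(self) -> float:
        if self.females_throughout == 0:
            return float("nan")
        return self.males_throughout / self.females_throughout


@dataclass
class OpenSimResult:
    """Observed robust-design capture matrix plus availability and truth."""

    matrix: CaptureMatrix  # observed individuals, primary_blocks metadata set
    presence: np.ndarray  # availability of the observed individuals per period
    truth: OpenTruth


def simulate_open(config: OpenSimConfig, rng=None) -> OpenSimResult:
    """Simulate one robust-design open-population study."""
    rng = _as_rng(config.seed if rng is None else rng)
    n_m, n_f = config.n_males, config.n_females
    # universe = starting residents plus an equally composed neighbour pool
    sex = np.array(
        ([SexLabel.MALE.value] * n_m + [SexLabel.FEMALE.value] * n_f) * 2, dtype="U6"
    )
    resident = np.zeros(2 * config.starting_population, dtype=bool)
    resident[: config.starting_population] = True
    state = PopulationState(sex=sex, resident=resident)

    t = config.periods
    det = np.zeros((len(sex), t), dtype=np.int8)
    presence = np.zeros((len(sex), t), dtype=bool)
    lo, hi = ClosedSimConfig(
        population_size=config.starting_population,
        captures_per_period=config.captures_per_period,
    ).capture_range
    male = sex == SexLabel.MALE.value
    for j in range(t):
        presence[:, j] = state.resident
        ss = lo if lo == hi else int(rng.integers(lo, hi + 1))
        male_ids = np.flatnonzero(state.resident & male)
        female_ids = np.flatnonzero(state.resident & ~male)
        if ss > len(male_ids) + len(female_ids):
            raise ValueError("captures_per_period exceeds resident population")
        caught = draw_weighted_sample(male_ids, female_ids, ss, config.bias, rng)
        det[caught, j] = 1
        # migration strictly between primary blocks
        if (j + 1) % config.secondaries == 0 and j + 1 < t:
            apply_migration(state, config.migration, rng)

    throughout = presence.all(axis=1)
    truth = OpenTruth(
        males_throughout=int((throughout & male).sum()),
        females_throughout=int((throughout & ~male).sum()),
        per_period_abundance=presence.sum(axis=0),
    )
    observed = det.sum(axis=1) > 0
    matrix = CaptureMatrix(
        det[observed],
        sex[observed],
        ids=np.flatnonzero(observed),
        primary_blocks=config.primary_blocks,
    )
    return OpenSimResult(matrix=matrix, presence=presence[observed], truth=truth)
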