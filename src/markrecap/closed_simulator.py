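"""Closed-population mark-recapture simulator with sex-biased catchability.

The population is demographically closed (no births, deaths, or movement).
In each sampling period a fixed number of distinct individuals is captured by
sequential weighted sampling without replacement: at every draw a remaining
male is selected with probability proportional to ``bias`` and a remaining
female proportional to 1, so males are ``bias`` times as likely to be caught
as females.  Being captured does not change an individual's catchability in
later periods (no trap response), and catchability does not vary over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .capture_data import CaptureMatrix, SexLabel

__all__ = [
    "ClosedSimConfig",
    "PopulationTruth",
    "ClosedSimResult",
    "draw_weighted_sample",
    "simulate_closed",
]


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class ClosedSimConfig:
    """Design of a closed-population simulation.

    Parameters
    ----------
    population_size
        True abundance N.
    proportion_male
        Fraction of the population that is male (0.5 = even sex ratio).
    captures_per_period
        Number of distinct individuals captured in each period; either a
        fixed integer or an inclusive ``(low, high)`` range from which the
        period's sample size is drawn uniformly.
    bias
        Relative catchability of males versus females (1 = equal, 1.5 =
        males 1.5 times as likely to be captured, ...).
    periods
        Number of sampling periods.
    seed
        Optional seed used when no generator is passed to the simulator.
    """

    population_size: int = 300
    proportion_male: float = 0.5
    captures_per_period: int | tuple[int, int] = 40
    bias: float = 1.0
    periods: int = 8
    seed: int | None = None

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 < self.proportion_male < 1.0:
            raise ValueError("proportion_male must be strictly between 0 and 1")
        if self.bias <= 0:
            raise ValueError("bias must be > 0")
        if self.periods < 2:
            raise ValueError("periods must be >= 2")
        lo, hi = self.capture_range
        if lo < 1 or hi < lo:
            raise ValueError("captures_per_period must be a positive int or (low, high)")
        if hi > self.population_size:
            raise ValueError(
                f"captures_per_period ({hi}) exceeds population_size "
                f"({self.population_size})"
            )

    @property
    def capture_range(self) -> tuple[int, int]:
        c = self.captures_per_period
        if isinstance(c, (tuple, list)):
            lo, hi = int(c[0]), int(c[1])
        else:
            lo = hi = int(c)
        return lo, hi

    @property
    def n_males(self) -> int:
        return int(round(self.population_size * self.proportion_male))

    @property
    def n_females(self) -> int:
        return self.population_size - self.n_males


@dataclass(frozen=True)
class PopulationTruth:
    """True state of a simulated population (includes never-captured animals)."""

    population_size: int
    n_males: int
    n_females: int

    @property
    def sex_ratio(self) -> float:
        return self.n_males / self.n_females


@dataclass
class ClosedSimResult:
    """Observed capture matrix plus the simulation truth record."""

    matrix: CaptureMatrix  # observed (captured at least once) individuals only
    truth: PopulationTruth
    sample_sizes: np.ndarray  # realised captures per period (column sums)


def draw_weighted_sample(male_ids, female_ids, n: int, bias: float, rng) -> np.ndarray:
    """Draw ``n`` distinct individuals, males ``bias`` times as catchable.

    Sequential weighted sampling without replacement: at each draw the
    probability of taking a particular remaining male is proportional to
    ``bias`` and a remaining female to 1.  Implemented by the exponential-race
    construction (draw Exp(w_i) arrival times and keep the ``n`` earliest),
    which realises exactly that sequential scheme.  The single-draw marginal
    is ``bias * n_males / (bias * n_males + n_females)``.
    """
    male_ids = np.asarray(male_ids)
    female_ids = np.asarray(female_ids)
    total = len(male_ids) + len(female_ids)
    if n > total:
        raise ValueError(f"cannot sample {n} from {total} available individuals")
    if bias <= 0:
        raise ValueError("bias must be > 0")
    rng = _as_rng(rng)
    ids = np.concatenate([male_ids, female_ids])
    weights = np.concatenate(
        [np.full(len(male_ids), float(bias)), np.ones(len(female_ids))]
    )
    keys = rng.exponential(size=total) / weights
    if n == total:
        return ids
    take = np.argpartition(keys, n)[:n]
    return ids[take]


def simulate_closed(config: ClosedSimConfig, rng=None) -> ClosedSimResult:
    """Simulate one closed-population mark-recapture study.

    Returns the capture histories of the observed individuals (animals never
    captured are part of the truth record but are not estimation input) along
    with the true population composition.
    """
    rng = _as_rng(config.seed if rng is None else rng)
    n_m, n_f = config.n_males, config.n_females
    sex = np.array(
        [SexLabel.MALE.value] * n_m + [SexLabel.FEMALE.value] * n_f, dtype="U6"
    )
    male_ids = np.arange(n_m)
    female_ids = np.arange(n_m, config.population_size)
    lo, hi = config.capture_range
    det = np.zeros((config.population_size, config.periods), dtype=np.int8)
    sizes = np.empty(config.periods, dtype=int)
    for j in range(config.periods):
        ss = lo if lo == hi else int(rng.integers(lo, hi + 1))
        caught = draw_weighted_sample(male_ids, female_ids, ss, config.bias, rng)
        det[caught, j] = 1
        sizes[j] = ss
    observed = det.sum(axis=1) > 0
    matrix = CaptureMatrix(
        det[observed], sex[observed], ids=np.flatnonzero(observed)
    )
    truth = PopulationTruth(config.population_size, n_m, n_f)
    return ClosedSimResult(matrix=matrix, truth=truth, sample_sizes=sizes)
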