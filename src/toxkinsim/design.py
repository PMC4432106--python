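"""Toxicology study designs: cohorts, dose groups, sampling schemes,
and random allocation of composite sampling slots to animals.

The three standard chronic-toxicity cohorts (1 week, 1 month, 3 months)
share the dose groups 0/10/30/100 mg/kg/day.  The main ("toxicity")
group is sampled sparsely by *composite* sampling — each scheduled time
point is covered by a fixed number of animals (3 by default), with the
slots allocated at random under the constraint that all animals are
sampled as equally as arithmetic allows.  The satellite group gives
full *serial* profiles.

Calendar mapping: 1 month = 28 days, week 4 = day 28, week 13 = day 91,
3 months = 91 days; all multiples of the 24-h dosing interval so that
steady-state days stay aligned.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, InfeasibleDesignError

__all__ = [
    "Scheme",
    "Role",
    "Duration",
    "SamplingScheme",
    "CohortDesign",
    "CompositeAllocation",
    "DEFAULT_TIMES",
    "build_cohort_design",
    "allocate_composite_samples",
    "design_table",
]

#: within-day sampling times (h after that day's dose)
DEFAULT_TIMES: tuple[float, ...] = (0.1, 0.4, 1.0, 1.5, 4.0, 8.0, 24.0)


class Scheme(str, Enum):
    COMPOSITE = "COMPOSITE"
    SERIAL = "SERIAL"


class Role(str, Enum):
    TOXICITY = "TOXICITY"
    SATELLITE = "SATELLITE"


class Duration(str, Enum):
    ONE_WEEK = "1_WEEK"
    ONE_MONTH = "1_MONTH"
    THREE_MONTHS = "3_MONTHS"


#: study duration in days of daily dosing
DURATION_DAYS: dict[Duration, int] = {
    Duration.ONE_WEEK: 7,
    Duration.ONE_MONTH: 28,
    Duration.THREE_MONTHS: 91,
}


@dataclass(frozen=True)
class SamplingScheme:
    scheme: Scheme
    sampling_days: tuple[int, ...]
    times_within_day: tuple[float, ...] = DEFAULT_TIMES
    replicates_per_timepoint: int = 3  # composite only

    def __post_init__(self) -> None:
        t = np.asarray(self.times_within_day)
        if t.size == 0 or np.any(np.diff(t) <= 0):
            raise ConfigurationError("times_within_day must be strictly increasing")
        if t.min() < 0 or t.max() > 24:
            raise ConfigurationError("times_within_day must lie in [0, 24]")
        if any(d < 1 for d in self.sampling_days):
            raise ConfigurationError("sampling days are 1-based study days")
        if self.replicates_per_timepoint < 1:
            raise ConfigurationError("replicates_per_timepoint must be >= 1")


@dataclass(frozen=True)
class CohortDesign:
    duration: Duration
    toxicity_n: int
    satellite_n: int
    toxicity_scheme: SamplingScheme
    satellite_scheme: SamplingScheme
    dose_groups: tuple[float, ...] = (0.0, 10.0, 30.0, 100.0)

    def __post_init__(self) -> None:
        if self.toxicity_n < 1 or self.satellite_n < 1:
            raise ConfigurationError("group sizes must be >= 1")
        ndays = DURATION_DAYS[self.duration]
        for sch in (self.toxicity_scheme, self.satellite_scheme):
            if max(sch.sampling_days) > ndays:
                raise ConfigurationError(
                    f"sampling day {max(sch.sampling_days)} beyond study "
                    f"duration ({ndays} days)"
                )

    @property
    def n_days(self) -> int:
        return DURATION_DAYS[self.duration]

    @property
    def last_serial_day(self) -> int:
        return max(self.satellite_scheme.sampling_days)

    def scheme_for(self, role: Role) -> SamplingScheme:
        return self.toxicity_scheme if role is Role.TOXICITY else self.satellite_scheme

    def group_size(self, role: Role) -> int:
        return self.toxicity_n if role is Role.TOXICITY else self.satellite_n


@dataclass
class CompositeAllocation:
    """Allocation of one day's composite slots: animal_id -> times (h)."""

    day: int
    times: tuple[float, ...]
    replicates_per_timepoint: int
    assignments: dict[int, list[float]]

    def animals_at(self, time: float) -> list[int]:
        return [a for a, ts in self.assignments.items() if time in ts]


# Table of standard cohorts: (toxicity_n, serial days, composite days)
_COHORTS: dict[Duration, tuple[int, tuple[int, ...], tuple[int, ...]]] = {
    Duration.ONE_WEEK: (4, (1,), (1,)),
    Duration.ONE_MONTH: (10, (1, 28), (1, 28)),
    Duration.THREE_MONTHS: (12, (1, 28, 91), (28, 91)),
}


def build_cohort_design(
    duration: Duration | str,
    overrides: Mapping[str, object] | None = None,
) -> CohortDesign:
    """Standard cohort design for a study duration, optionally overridden.

    Override keys: ``toxicity_n``, ``satellite_n``, ``dose_groups``,
    ``times_within_day``, ``replicates_per_timepoint``,
    ``serial_days``, ``composite_days``.
    """
    duration = Duration(duration)
    tox_n, serial_days, composite_days = _COHORTS[duration]
    ov = dict(overrides or {})
    times = tuple(ov.pop("times_within_day", DEFAULT_TIMES))
    reps = int(ov.pop("replicates_per_timepoint", 3))
    serial_days = tuple(ov.pop("serial_days", serial_days))
    composite_days = tuple(ov.pop("composite_days", composite_days))
    design = CohortDesign(
        duration=duration,
        toxicity_n=int(ov.pop("toxicity_n", tox_n)),
        satellite_n=int(ov.pop("satellite_n", 3)),
        dose_groups=tuple(ov.pop("dose_groups", (0.0, 10.0, 30.0, 100.0))),
        toxicity_scheme=SamplingScheme(
            Scheme.COMPOSITE, composite_days, times, reps),
        satellite_scheme=SamplingScheme(
            Scheme.SERIAL, serial_days, times, reps),
    )
    if ov:
        raise ConfigurationError(f"unknown design overrides: {sorted(ov)}")
    return design


def allocate_composite_samples(
    n_animals: int,
    times: Sequence[float],
    replicates_per_timepoint: int,
    rng: int | np.random.Generator,
    day: int = 1,
    animal_ids: Sequence[int] | None = None,
) -> CompositeAllocation:
    """Randomly assign composite sampling slots to animals.

    Every time point is covered by exactly ``replicates_per_timepoint``
    distinct animals, and per-animal sample counts differ by at most one
    across the group (the equal-sampling constraint).  Seeded draws are
    reproducible.
    """
    if n_animals < 1:
        raise ConfigurationError("n_animals must be >= 1")
    times = tuple(float(t) for t in times)
    n_times, r = len(times), replicates_per_timepoint
    if r > n_animals:
        raise InfeasibleDesignError(
            f"{r} distinct animals per time point requested but only "
            f"{n_animals} animals available"
        )
    total = n_times * r
    base, extra = divmod(total, n_animals)
    if base + (1 if extra else 0) > n_times:
        raise InfeasibleDesignError(
            "per-animal sample count would exceed the number of time points"
        )
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if animal_ids is None:
        animal_ids = list(range(1, n_animals + 1))
    animal_ids = list(animal_ids)

    remaining = np.full(n_animals, base, dtype=float)
    remaining[gen.choice(n_animals, size=extra, replace=False)] += 1
    assignments: dict[int, list[float]] = {a: [] for a in animal_ids}
    # serve time points in random order; at each, pick the r animals with
    # the most outstanding slots (random tie-break keeps the draw uniform
    # over feasible schedules in spirit, and balanced counts guarantee
    # feasibility of the greedy choice)
    for ti in gen.permutation(n_times):
        jitter = gen.random(n_animals) * 0.5
        order = np.argsort(-(remaining + jitter), kind="stable")
        chosen = order[:r]
        if np.any(remaining[chosen] <= 0):
            raise InfeasibleDesignError("composite slot allocation failed")
        remaining[chosen] -= 1
        for a in chosen:
            assignments[animal_ids[a]].append(times[ti])
    for a in assignments:
        assignments[a].sort()
    return CompositeAllocation(
        day=day, times=times, replicates_per_timepoint=r, assignments=assignments
    )


def design_table(design: CohortDesign) -> "pandas.DataFrame":
    """Realized sampling table (one row per group x role x day), used by
    the design linter/CLI."""
    import pandas as pd

    rows = []
    for dose in design.dose_groups:
        for role in Role:
            sch = design.scheme_for(role)
            for day in sch.sampling_days:
                n = design.group_size(role)
                n_samples = (
                    len(sch.times_within_day) * sch.replicates_per_timepoint
                    if sch.scheme is Scheme.COMPOSITE
                    else len(sch.times_within_day) * n
                )
                rows.append({
                    "dose_mg_kg": dose,
                    "role": role.value,
                    "scheme": sch.scheme.value,
                    "day": day,
                    "n_animals": n,
                    "n_samples": n_samples,
                    "times_h": ",".join(str(t) for t in sch.times_within_day),
                })
    return pd.DataFrame(rows)
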