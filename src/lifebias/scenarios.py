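"""Survival-target schedules for the four study scenarios.

Each scenario assigns every birth year ``t = 1..horizon`` a pair of survival
targets ``(mean m(t), median d(t))``:

1. **Constant** — ``(25.3, 20.8)`` for all ``t``.
2. **Gradual improvement** — both targets increase by 0.05 years per year
   from the base, i.e. ``m(t) = 25.3 + 0.05 (t - 1)``.
3. **Improvement then plateau** — as scenario 2 up to the change year (460),
   then frozen at the change-year values ``(48.25, 43.75)``.
4. **Plateau then rapid improvement** — constant at the base until the change
   year, then both targets increase by 0.5 years per year:
   ``m(t) = 25.3 + 0.5 (t - 460)`` for ``t >= 460``.

The "true" life expectancy a study window should recover is the arithmetic
average of the scheduled targets over the window birth years (465..500 by
default, 36 years).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterator, Sequence

import numpy as np

from .weibull import TargetMoments, solve_weibull

__all__ = [
    "ScenarioConfig",
    "ScenarioSchedule",
    "build_schedule",
    "true_window_values",
]

SCENARIO_IDS = (1, 2, 3, 4)


@dataclass(frozen=True)
class ScenarioConfig:
    """Configuration of one simulation scenario.

    Defaults are the study conditions: a 500-year horizon with one birth per
    year, base survival targets (mean 25.3, median 20.8) years, a slow
    improvement slope of 0.05 years/year, a fast slope of 0.5 years/year, a
    change point at year 460, and an observation window [465, 500].
    """

    scenario_id: int
    horizon_years: int = 500
    base_mean: float = 25.3
    base_median: float = 20.8
    slow_slope: float = 0.05
    fast_slope: float = 0.5
    change_year: int = 460
    window_start: int = 465
    window_end: int = 500

    def __post_init__(self) -> None:
        if self.scenario_id not in SCENARIO_IDS:
            raise ValueError(
                f"unknown scenario_id {self.scenario_id!r}; expected one of {SCENARIO_IDS}"
            )
        if not (1 <= self.change_year <= self.horizon_years):
            raise ValueError("change_year must lie within 1..horizon_years")
        if not (self.window_start <= self.window_end <= self.horizon_years):
            raise ValueError("window must satisfy window_start <= window_end <= horizon_years")
        if self.slow_slope < 0 or self.fast_slope < 0:
            raise ValueError("slopes must be non-negative")
        TargetMoments(self.base_mean, self.base_median)  # validates positivity

    @property
    def base_moments(self) -> TargetMoments:
        return TargetMoments(self.base_mean, self.base_median)

    @property
    def window_years(self) -> range:
        """Birth years inside the observation window (inclusive ends)."""
        return range(self.window_start, self.window_end + 1)


class ScenarioSchedule(Sequence[TargetMoments]):
    """Per-birth-year survival targets for years ``t = 1..horizon``.

    Indexable by 0-based position; :meth:`for_year` takes the 1-based birth
    year.  Weibull parameters for every year are solved lazily and cached, so
    the per-year inversions happen once per schedule rather than once per
    simulated replicate.
    """

    def __init__(self, targets: Sequence[TargetMoments]):
        self._targets: tuple[TargetMoments, ...] = tuple(targets)
        if not self._targets:
            raise ValueError("schedule must contain at least one year")

    def __len__(self) -> int:
        return len(self._targets)

    def __getitem__(self, i):  # type: ignore[override]
        return self._targets[i]

    def __iter__(self) -> Iterator[TargetMoments]:
        return iter(self._targets)

    def for_year(self, year: int) -> TargetMoments:
        """Targets for 1-based birth year ``year``."""
        if not (1 <= year <= len(self._targets)):
            raise IndexError(f"year {year} outside 1..{len(self._targets)}")
        return self._targets[year - 1]

    @cached_property
    def weibull_params(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays ``(scales, shapes)`` solved from the per-year targets."""
        params = [solve_weibull(t) for t in self._targets]
        scales = np.array([p.scale for p in params])
        shapes = np.array([p.shape for p in params])
        return scales, shapes

    @property
    def means(self) -> np.ndarray:
        return np.array([t.mean for t in self._targets])

    @property
    def medians(self) -> np.ndarray:
        return np.array([t.median for t in self._targets])


def _targets_for_year(config: ScenarioConfig, t: int) -> TargetMoments:
    m0, d0 = config.base_mean, config.base_median
    s = config.scenario_id
    if s == 1:
        return TargetMoments(m0, d0)
    if s == 2:
        shift = config.slow_slope * (t - 1)
    elif s == 3:
        shift = config.slow_slope * (min(t, config.change_year) - 1)
    else:  # scenario 4
        shift = config.fast_slope * max(t - config.change_year, 0)
    return TargetMoments(m0 + shift, d0 + shift)


def build_schedule(config: ScenarioConfig) -> ScenarioSchedule:
    """Build the per-birth-year target schedule for ``config``'s scenario."""
    return ScenarioSchedule(
        [_targets_for_year(config, t) for t in range(1, config.horizon_years + 1)]
    )


def true_window_values(
    schedule: ScenarioSchedule, config: ScenarioConfig
) -> TargetMoments:
    """Analytic true values: window averages of the scheduled mean and median.

    Averages ``m(t)`` and ``d(t)`` over the birth years
    ``window_start..window_end`` inclusive (36 years at defaults).
    """
    years = config.window_years
    if len(years) == 0:
        raise ValueError("empty observation window")
    entries = [schedule.for_year(t) for t in years]
    return TargetMoments(
        mean=float(np.mean([e.mean for e in entries])),
        median=float(np.mean([e.median for e in entries])),
    )
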