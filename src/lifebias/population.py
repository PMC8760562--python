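"""Population simulator: one birth per year, Weibull lifespans per birth year.

A population is one full realisation of the birth-death process: exactly one
individual born at each integer year ``t = 1..horizon``, with a lifespan drawn
from the Weibull distribution solved from that birth year's survival targets.
Individuals are mutually independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenarios import ScenarioConfig, ScenarioSchedule

__all__ = ["Individual", "Population", "simulate_population"]


@dataclass(frozen=True)
class Individual:
    """One simulated person: birth time and lifespan on the simulation clock."""

    birth_time: float
    lifespan: float

    def __post_init__(self) -> None:
        if not (self.lifespan > 0.0):
            raise ValueError(f"lifespan must be positive, got {self.lifespan}")

    @property
    def death_time(self) -> float:
        return self.birth_time + self.lifespan


@dataclass
class Population:
    """All individuals of one replicate, stored columnwise.

    ``birth_times`` are strictly increasing (one birth per year); lifespans
    are strictly positive.
    """

    birth_times: np.ndarray
    lifespans: np.ndarray

    def __post_init__(self) -> None:
        self.birth_times = np.asarray(self.birth_times, dtype=float)
        self.lifespans = np.asarray(self.lifespans, dtype=float)
        if self.birth_times.shape != self.lifespans.shape:
            raise ValueError("birth_times and lifespans must have equal length")
        if np.any(np.diff(self.birth_times) <= 0):
            raise ValueError("birth times must be strictly increasing")
        if np.any(self.lifespans <= 0):
            raise ValueError("all lifespans must be positive")

    def __len__(self) -> int:
        return self.birth_times.size

    @property
    def death_times(self) -> np.ndarray:
        return self.birth_times + self.lifespans

    @property
    def individuals(self) -> list[Individual]:
        return [Individual(b, s) for b, s in zip(self.birth_times, self.lifespans)]

    def to_frame(self) -> pd.DataFrame:
        """Columns (birth_time, lifespan, death_time), for CSV dumps."""
        return pd.DataFrame(
            {
                "birth_time": self.birth_times,
                "lifespan": self.lifespans,
                "death_time": self.death_times,
            }
        )


def simulate_population(
    schedule: ScenarioSchedule, config: ScenarioConfig, rng: np.random.Generator
) -> Population:
    """Simulate one population under ``schedule``.

    Births occur at exact integer times ``t = 1..horizon`` (no within-year
    jitter); individual ``t``'s lifespan is one Weibull draw at the
    schedule's year-``t`` parameters.  The per-year parameter inversions are
    cached on the schedule, so repeated replicates re-use them.
    """
    if len(schedule) != config.horizon_years:
        raise ValueError(
            f"schedule length {len(schedule)} != horizon {config.horizon_years}"
        )
    scales, shapes = schedule.weibull_params
    births = np.arange(1, config.horizon_years + 1, dtype=float)
    lifespans = scales * rng.weibull(shapes)
    return Population(birth_times=births, lifespans=lifespans)
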