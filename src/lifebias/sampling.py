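"""Observation samples drawn from a simulated population.

Four ways of observing the same population through the study window
``[window_start, window_end]`` (465..500 by default), mirroring how real
life-expectancy studies collect data:

* **period** — complete lifespans of individuals who *died* inside the
  window (a retrospective death-record review);
* **cohort** — complete lifespans of individuals *born* inside the window,
  even when death occurs after the horizon (the idealised follow-up);
* **retrospective** — everyone who died since the window start, with
  individuals still alive at the horizon right-censored there.  Entry at
  birth; left truncation is deliberately ignored, since that is exactly the
  bias mechanism under study;
* **prospective** — everyone born since the window start, right-censored at
  the horizon.

Censoring weights for the weighted Kaplan-Meier variants are attached with
:func:`assign_weights`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .population import Population
from .scenarios import ScenarioConfig

__all__ = [
    "SurvivalRecord",
    "SurvivalSample",
    "period_sample",
    "cohort_sample",
    "retrospective_sample",
    "prospective_sample",
    "assign_weights",
]

WEIGHT_SCHEMES = ("unit", "fixed", "uncensored_percentage")


@dataclass(frozen=True)
class SurvivalRecord:
    """One (observed time, event flag, weight) observation."""

    observed_time: float
    event: bool
    weight: float = 1.0


@dataclass
class SurvivalSample:
    """Censored survival observations stored columnwise.

    ``times`` are observed times (years), ``events`` flags observed deaths
    (False = censored at the horizon), ``weights`` lie in (0, 1].  Event
    times are strictly positive; a censored time may be 0 (an individual
    born exactly at the horizon has no follow-up).
    """

    times: np.ndarray
    events: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=bool)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (self.times.shape == self.events.shape == self.weights.shape):
            raise ValueError("times, events and weights must have equal length")
        if np.any(self.times < 0):
            raise ValueError("observed times must be non-negative")
        if np.any(self.times[self.events] <= 0):
            raise ValueError("event times must be strictly positive")
        if np.any((self.weights <= 0) | (self.weights > 1)):
            raise ValueError("weights must lie in (0, 1]")

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @property
    def n_censored(self) -> int:
        return len(self) - self.n_events

    @property
    def records(self) -> list[SurvivalRecord]:
        return [
            SurvivalRecord(float(t), bool(e), float(w))
            for t, e, w in zip(self.times, self.events, self.weights)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "event": self.events, "weight": self.weights}
        )


def period_sample(pop: Population, config: ScenarioConfig) -> np.ndarray:
    """Complete lifespans of individuals who died within the window.

    Selects ``window_start <= death_time <= window_end``; every returned
    value is a full, uncensored lifespan.  May be empty.
    """
    death = pop.death_times
    mask = (death >= config.window_start) & (death <= config.window_end)
    return pop.lifespans[mask].copy()


def cohort_sample(pop: Population, config: ScenarioConfig) -> np.ndarray:
    """Complete lifespans of individuals born within the window.

    Selects ``window_start <= birth_time <= window_end`` and keeps the full
    lifespan even when death occurs after the horizon (36 individuals at
    defaults).
    """
    birth = pop.birth_times
    mask = (birth >= config.window_start) & (birth <= config.window_end)
    return pop.lifespans[mask].copy()


def _censored_at_horizon(
    pop: Population, mask: np.ndarray, horizon: float
) -> SurvivalSample:
    birth = pop.birth_times[mask]
    death = pop.death_times[mask]
    times = np.minimum(death, horizon) - birth
    events = death <= horizon
    return SurvivalSample(times=times, events=events, weights=np.ones_like(times))


def retrospective_sample(pop: Population, config: ScenarioConfig) -> SurvivalSample:
    """Everyone who died since the window start, censored at the horizon.

    Includes individuals whose true death occurs after the horizon — they
    appear as censored records.  Observation starts at birth (no delayed
    entry), which reproduces the length bias of naive death-record sampling.
    """
    mask = pop.death_times >= config.window_start
    return _censored_at_horizon(pop, mask, config.horizon_years)


def prospective_sample(pop: Population, config: ScenarioConfig) -> SurvivalSample:
    """Everyone born since the window start, censored at the horizon.

    36 individuals at defaults; those still alive at the horizon are
    right-censored there.
    """
    mask = pop.birth_times >= config.window_start
    return _censored_at_horizon(pop, mask, config.horizon_years)


def assign_weights(
    sample: SurvivalSample, scheme: str, w: float | None = None
) -> SurvivalSample:
    """Return a copy of ``sample`` with censored records re-weighted.

    Event records always keep weight 1.  Censored records get weight

    * ``"unit"`` — 1 (standard Kaplan-Meier);
    * ``"fixed"`` — the supplied ``w`` in (0, 1];
    * ``"uncensored_percentage"`` — the fraction of event records among all
      records, ``n_events / (n_events + n_censored)``, computed on this
      sample.

    Raises
    ------
    ValueError
        For an unknown scheme, a fixed ``w`` outside (0, 1], or an
        ``uncensored_percentage`` request on an empty or zero-event sample
        (a zero weight is not allowed).
    """
    if scheme not in WEIGHT_SCHEMES:
        raise ValueError(f"unknown weighting scheme {scheme!r}; expected one of {WEIGHT_SCHEMES}")
    if scheme == "unit":
        cens_weight = 1.0
    elif scheme == "fixed":
        if w is None or not (0.0 < w <= 1.0):
            raise ValueError(f"fixed scheme needs a weight in (0, 1], got {w}")
        cens_weight = float(w)
    else:
        if len(sample) == 0:
            raise ValueError("uncensored_percentage is undefined for an empty sample")
        if sample.n_events == 0:
            raise ValueError(
                "uncensored_percentage would give censored records weight 0 "
                "(no events in sample)"
            )
        cens_weight = sample.n_events / len(sample)
    weights = np.where(sample.events, 1.0, cens_weight)
    return replace(
        sample,
        times=sample.times.copy(),
        events=sample.events.copy(),
        weights=weights,
    )
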