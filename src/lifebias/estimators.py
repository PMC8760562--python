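"""Life-expectancy estimators: complete-data moments and (weighted) Kaplan-Meier.

The weighted product-limit estimator generalises Kaplan-Meier by letting each
record contribute its weight to the risk set and event counts:

.. math::

    \\hat S(t_j) = \\prod_{i \\le j} \\left(1 - \\frac{D_i}{Y_i}\\right),

where :math:`t_1 < t_2 < \\dots` are the distinct event times, :math:`D_i`
is the total weight of events at :math:`t_i` and :math:`Y_i` is the total
weight of records with observed time :math:`\\ge t_i`.  Event records carry
weight 1, so down-weighting censored records damps their inflation of the
risk set.  With all weights 1 the estimator is the standard Kaplan-Meier; as
the censored weight tends to 0 it tends to the empirical survival curve of
the event records alone.

Tie convention: censored records tied with an event time remain in the risk
set for that event (censoring happens "just after" deaths), the usual
Kaplan-Meier rule.

The estimated median is the smallest event time at which the curve drops to
0.5 or below; if the curve never does, the median is *not reached* and is
reported as ``None``.  Two complete-data medians are provided:
:func:`sample_median` follows the same first-crossing (order-statistic)
convention, so it coincides with the Kaplan-Meier median of the all-events
sample identically — the convention used for period (death-record) medians —
while :func:`complete_median` is the ordinary midpoint-interpolated median
used to summarise fully observed cohort lifespans.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .sampling import SurvivalSample

__all__ = [
    "KMCurve",
    "MedianEstimate",
    "complete_mean",
    "complete_median",
    "sample_median",
    "km_fit",
    "km_median",
]

#: A median estimate: years, or ``None`` when the curve never reaches 0.5.
MedianEstimate = Optional[float]

# Absolute slack when testing S(t) against 0.5, so that survival probabilities
# that are exactly one half up to float rounding are recognised as such.
_MEDIAN_EPS = float(np.finfo(float).eps ** 0.5)


@dataclass
class KMCurve:
    """Estimated survival curve: survival probabilities at the event times.

    ``survival[j]`` is the curve evaluated at ``times[j]`` (right-continuous
    step function; survival is 1 before the first event time).
    """

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times.shape != self.survival.shape:
            raise ValueError("times and survival must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any((self.survival < -1e-12) | (self.survival > 1 + 1e-12)):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival})


def complete_mean(lifespans: Sequence[float]) -> Optional[float]:
    """Arithmetic mean of complete (uncensored) lifespans; ``None`` if empty."""
    arr = np.asarray(lifespans, dtype=float)
    if arr.size == 0:
        return None
    return float(arr.mean())


def sample_median(lifespans: Sequence[float]) -> Optional[float]:
    """Median of complete lifespans, as the ceil(n/2)-th order statistic.

    This is exactly the Kaplan-Meier median of the same values treated as an
    all-events sample (the first order statistic at which the empirical
    survival drops to one half or below), so period medians and no-censoring
    KM medians agree identically.  No midpoint interpolation for even n.
    Returns ``None`` for an empty input.
    """
    arr = np.sort(np.asarray(lifespans, dtype=float))
    n = arr.size
    if n == 0:
        return None
    return float(arr[(n + 1) // 2 - 1])


def complete_median(lifespans: Sequence[float]) -> Optional[float]:
    """Ordinary sample median (midpoint-interpolated for even n).

    Used for cohort estimates, which summarise fully observed lifespans with
    the standard descriptive median rather than the survival-curve
    convention.  Returns ``None`` for an empty input.
    """
    arr = np.asarray(lifespans, dtype=float)
    if arr.size == 0:
        return None
    return float(np.median(arr))


def km_fit(sample: SurvivalSample) -> KMCurve:
    """Weighted product-limit fit of a censored survival sample.

    Requires at least one event record.  Should the weighted risk set hit
    zero before the last event time (impossible with positive weights, but
    guarded), the curve is truncated at the last positive-risk time.
    """
    if sample.n_events == 0:
        raise ValueError("Kaplan-Meier fit requires at least one event record")

    event_times = sample.times[sample.events]
    event_weights = sample.weights[sample.events]
    uniq, inverse = np.unique(event_times, return_inverse=True)
    d = np.bincount(inverse, weights=event_weights)

    # Risk set at t_j: total weight of records with observed time >= t_j.
    order = np.argsort(sample.times, kind="stable")
    sorted_times = sample.times[order]
    suffix = np.concatenate(
        [np.cumsum(sample.weights[order][::-1])[::-1], [0.0]]
    )
    y = suffix[np.searchsorted(sorted_times, uniq, side="left")]

    positive = y > 0
    if not positive.all():
        cut = int(np.argmin(positive))  # first zero-risk event time
        uniq, d, y = uniq[:cut], d[:cut], y[:cut]
    survival = np.cumprod(1.0 - d / y)
    return KMCurve(times=uniq, survival=np.clip(survival, 0.0, 1.0))


def km_median(curve: KMCurve) -> MedianEstimate:
    """Smallest event time with survival <= 0.5; ``None`` if never reached."""
    hit = np.nonzero(curve.survival <= 0.5 + _MEDIAN_EPS)[0]
    if hit.size == 0:
        return None
    return float(curve.times[hit[0]])
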